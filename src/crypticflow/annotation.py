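"""Transcript-annotation index for junction and peak classification.

Builds, from a GTF, the set of annotated splice junctions (the interval
between consecutive exons of each transcript), strand-aware donor/acceptor
site sets, per-gene intron intervals, and feature interval trees (CDS, UTRs,
exons, introns split by coding/non-coding biotype) used by the peak-annotation
priority hierarchy.

All internal coordinates are 0-based half-open; GTF input (1-based inclusive)
is converted on read.
"""

from __future__ import annotations

import collections
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import gffutils
from intervaltree import IntervalTree

#: peak annotation categories, highest priority first
ANNOTATION_PRIORITY = ("CDS", "5UTR", "3UTR", "pc_intron", "nc_exon", "nc_intron")

_CODING_BIOTYPES = {"protein_coding"}


@dataclass
class Intron:
    chrom: str
    start: int
    end: int
    strand: str
    gene_id: str
    transcript_id: str


@dataclass
class AnnotationIndex:
    """Strand-aware lookup structures derived from a transcript annotation."""

    junctions: set[tuple[str, int, int, str]] = field(default_factory=set)
    donors: set[tuple[str, int, str]] = field(default_factory=set)
    acceptors: set[tuple[str, int, str]] = field(default_factory=set)
    introns: dict[tuple[str, str], IntervalTree] = field(
        default_factory=lambda: collections.defaultdict(IntervalTree)
    )
    features: dict[tuple[str, str], dict[str, IntervalTree]] = field(
        default_factory=lambda: collections.defaultdict(
            lambda: {cat: IntervalTree() for cat in ANNOTATION_PRIORITY}
        )
    )
    genes: dict[tuple[str, str], IntervalTree] = field(
        default_factory=lambda: collections.defaultdict(IntervalTree)
    )

    # -- junction queries ---------------------------------------------------
    def has_junction(self, chrom: str, start: int, end: int, strand: str) -> bool:
        """Exact-coordinate, strand-aware membership of an intron interval."""
        if strand in "+-":
            return (chrom, start, end, strand) in self.junctions
        # unknown strand: match either strand
        return any((chrom, start, end, s) in self.junctions for s in "+-")

    def has_donor(self, chrom: str, pos: int, strand: str) -> bool:
        if strand in "+-":
            return (chrom, pos, strand) in self.donors
        return any((chrom, pos, s) in self.donors for s in "+-")

    def has_acceptor(self, chrom: str, pos: int, strand: str) -> bool:
        if strand in "+-":
            return (chrom, pos, strand) in self.acceptors
        return any((chrom, pos, s) in self.acceptors for s in "+-")

    def introns_containing(self, chrom: str, start: int, end: int, strand: str) -> list[Intron]:
        """Annotated introns fully containing [start, end)."""
        strands = [strand] if strand in "+-" else ["+", "-"]
        out = []
        for s in strands:
            for iv in self.introns[(chrom, s)].overlap(start, end):
                if iv.begin <= start and end <= iv.end:
                    out.append(iv.data)
        return out

    def genes_overlapping(self, chrom: str, start: int, end: int, strand: str) -> set[str]:
        strands = [strand] if strand in "+-" else ["+", "-"]
        hits: set[str] = set()
        for s in strands:
            hits.update(iv.data for iv in self.genes[(chrom, s)].overlap(start, end))
        return hits


def _biotype(feature: gffutils.Feature) -> str:
    for key in ("transcript_biotype", "transcript_type", "gene_biotype", "gene_type"):
        if key in feature.attributes:
            return feature.attributes[key][0]
    return "protein_coding"


def _exons_of(db: gffutils.FeatureDB, tx: gffutils.Feature) -> list[tuple[int, int]]:
    exons = [(e.start - 1, e.end) for e in db.children(tx, featuretype="exon")]
    return sorted(exons)


def build_annotation_index(gtf_path: str | Path) -> AnnotationIndex:
    """Index a GTF: annotated junctions, splice sites, introns, feature trees.

    Annotated junction = interval between the end of exon *i* and the start of
    exon *i+1* of the same transcript (duplicates across transcripts
    collapsed).  Exons are sorted per transcript, so unsorted GTFs are
    handled.  A missing ``transcript_id`` raises ``ValueError``.
    """
    db = gffutils.create_db(
        str(gtf_path),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    index = AnnotationIndex()

    # group exons and CDS by transcript directly: robust to GTFs without
    # explicit transcript features
    tx_exons: dict[str, list[tuple[int, int]]] = collections.defaultdict(list)
    tx_cds: dict[str, list[tuple[int, int]]] = collections.defaultdict(list)
    tx_meta: dict[str, tuple[str, str, str, str]] = {}  # chrom, strand, gene, biotype
    for feat in db.all_features():
        if feat.featuretype not in ("exon", "CDS"):
            continue
        if "transcript_id" not in feat.attributes:
            raise ValueError(
                f"{feat.featuretype} feature at {feat.seqid}:{feat.start}-{feat.end} "
                "lacks a transcript_id attribute"
            )
        tid = feat.attributes["transcript_id"][0]
        gene = feat.attributes.get("gene_id", [tid])[0]
        tx_meta.setdefault(tid, (feat.seqid, feat.strand, gene, _biotype(feat)))
        iv = (feat.start - 1, feat.end)
        (tx_exons if feat.featuretype == "exon" else tx_cds)[tid].append(iv)

    for tid, exons in tx_exons.items():
        chrom, strand, gene, biotype = tx_meta[tid]
        coding = biotype in _CODING_BIOTYPES
        exons = sorted(exons)
        key = (chrom, strand)
        index.genes[key].addi(exons[0][0], exons[-1][1], gene)
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            index.junctions.add((chrom, e1, s2, strand))
            if strand == "-":
                index.donors.add((chrom, s2, strand))
                index.acceptors.add((chrom, e1, strand))
            else:
                index.donors.add((chrom, e1, strand))
                index.acceptors.add((chrom, s2, strand))
            index.introns[key].addi(e1, s2, Intron(chrom, e1, s2, strand, gene, tid))
            intron_cat = "pc_intron" if coding else "nc_intron"
            index.features[key][intron_cat].addi(e1, s2, gene)

        cds = sorted(tx_cds.get(tid, []))
        if coding and cds:
            cds_lo, cds_hi = cds[0][0], cds[-1][1]
            for s, e in cds:
                index.features[key]["CDS"].addi(s, e, gene)
            for s, e in exons:
                # exonic sequence outside the CDS span is UTR; side depends
                # on strand
                if s < cds_lo:
                    left = (s, min(e, cds_lo))
                    cat = "5UTR" if strand != "-" else "3UTR"
                    index.features[key][cat].addi(*left, gene)
                if e > cds_hi:
                    right = (max(s, cds_hi), e)
                    cat = "3UTR" if strand != "-" else "5UTR"
                    index.features[key][cat].addi(*right, gene)
        elif not coding:
            for s, e in exons:
                index.features[key]["nc_exon"].addi(s, e, gene)
        else:
            # coding biotype without CDS records: treat exons as CDS-less
            # coding exons -> count as CDS for the hierarchy
            for s, e in exons:
                index.features[key]["CDS"].addi(s, e, gene)

    return index


def annotated_junctions(index: AnnotationIndex) -> Iterable[tuple[str, int, int, str]]:
    return sorted(index.junctions)
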