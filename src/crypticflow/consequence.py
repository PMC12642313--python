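"""Protein-level consequence of a cryptic-exon (CE) inclusion.

Given a transcript model, a CE interval inside one of its introns and the
genome sequence, this module assembles the CE-containing mature mRNA,
translates from the annotated start codon to the first stop, extracts the
cryptic peptide (residues whose codons begin inside the CE), and applies the
50-nt rule to flag nonsense-mediated-decay (NMD) candidates.

Coordinates: genomic intervals are 0-based half-open; transcript coordinates
run 5'→3' along the mature mRNA.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import gffutils
from Bio.Seq import Seq


@dataclass
class TranscriptModel:
    """A spliced transcript: ordered genomic exons plus CDS in transcript coordinates."""

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]  # genomic, ascending, non-overlapping
    cds_start: int  # transcript coordinate of the A of ATG
    cds_end: int  # transcript coordinate one past the stop codon

    def __post_init__(self) -> None:
        exons = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if e1 > s2:
                raise ValueError("exons overlap")
        self.exons = exons
        tx_len = sum(e - s for s, e in exons)
        if not (0 <= self.cds_start < self.cds_end <= tx_len):
            raise ValueError("CDS outside transcript bounds")

    @property
    def introns(self) -> list[tuple[int, int]]:
        return [(e1, s2) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])]


@dataclass
class SplicedTranscript:
    """Mature mRNA with (optionally) a cryptic exon spliced in."""

    seq: str
    cds_start: int
    ce_tx: tuple[int, int] | None  # CE span in transcript coordinates, or None
    junctions_tx: list[int] = field(default_factory=list)  # exon-exon junction positions


@dataclass
class ProteinProduct:
    protein: str  # residues up to (not including) the stop
    cryptic_suffix: str  # residues whose codon's first base lies in the CE
    stop_in_ce: bool
    truncated: bool | None  # None when no reference length was given
    stop_tx_start: int | None  # transcript coordinate of the stop codon; None if non-stop
    non_stop: bool
    nmd_candidate: bool | None = None

    @property
    def length(self) -> int:
        return len(self.protein)


def _revcomp(s: str) -> str:
    return str(Seq(s).reverse_complement())


def _assemble(pieces: list[tuple[int, int]], chrom_seq: str, strand: str) -> str:
    plus = "".join(chrom_seq[s:e] for s, e in pieces)
    return _revcomp(plus) if strand == "-" else plus


def _tx_coords(pieces: list[tuple[int, int]], strand: str):
    """Map each genomic piece to its transcript-coordinate span."""
    lengths = [e - s for s, e in pieces]
    total = sum(lengths)
    spans = []
    off = 0
    for ln in lengths:
        spans.append((off, off + ln))
        off += ln
    if strand == "-":
        spans = [(total - e, total - s) for s, e in spans][::-1]
        # keep spans aligned with 5'→3' piece order on the minus strand
    return spans, total


def mature_mrna(model: TranscriptModel, genome: Mapping[str, str]) -> SplicedTranscript:
    """Reference mature mRNA of the model (no cryptic exon)."""
    chrom_seq = genome[model.chrom]
    seq = _assemble(model.exons, chrom_seq, model.strand)
    spans, _ = _tx_coords(model.exons, model.strand)
    junctions = sorted(e for _, e in spans)[:-1]  # drop transcript end
    return SplicedTranscript(seq=seq, cds_start=model.cds_start, ce_tx=None, junctions_tx=junctions)


def splice_in_ce(
    model: TranscriptModel, ce_interval: tuple[int, int], genome: Mapping[str, str]
) -> SplicedTranscript:
    """Mature mRNA with the CE inserted between its flanking exons.

    ``ce_interval`` (genomic, 0-based half-open) must lie strictly inside one
    intron of the model; a CE touching or overlapping an exon is rejected.
    On the minus strand the assembly is the reverse complement of the
    plus-strand concatenation and the CE transcript span is mapped
    accordingly.  ``cds_start`` is shifted if the CE lands upstream of the
    start codon (it cannot for an intronic CE downstream of the CDS start,
    but the general arithmetic is kept).
    """
    ce_s, ce_e = ce_interval
    if ce_e <= ce_s:
        raise ValueError("empty cryptic-exon interval")
    host = None
    for istart, iend in model.introns:
        if istart < ce_s and ce_e < iend:
            host = (istart, iend)
            break
        if ce_s < iend and ce_e > istart:  # overlaps this intron but not strictly inside
            raise ValueError(
                f"cryptic exon [{ce_s},{ce_e}) is not strictly inside intron [{istart},{iend})"
            )
    if host is None:
        raise ValueError(f"cryptic exon [{ce_s},{ce_e}) lies in no intron of {model.transcript_id}")

    pieces: list[tuple[int, int]] = []
    for s, e in model.exons:
        pieces.append((s, e))
        if e == host[0]:
            pieces.append((ce_s, ce_e))
    chrom_seq = genome[model.chrom]
    seq = _assemble(pieces, chrom_seq, model.strand)
    spans, total = _tx_coords(pieces, model.strand)

    # locate the CE piece's transcript span
    idx = pieces.index((ce_s, ce_e))
    if model.strand == "-":
        # spans were re-ordered 5'→3'; recompute position of the CE piece
        plus_spans = []
        off = 0
        for s, e in pieces:
            plus_spans.append((off, off + (e - s)))
            off += e - s
        ps, pe = plus_spans[idx]
        ce_tx = (total - pe, total - ps)
        junctions = sorted({total - sp[1] for sp in plus_spans} | {total - sp[0] for sp in plus_spans})
        junctions = [j for j in junctions if 0 < j < total]
    else:
        ce_tx = spans[idx]
        junctions = [e for _, e in spans][:-1]

    # transcript-coordinate CDS start: exonic CE downstream of the start codon
    # leaves it unchanged; a CE 5' of the start shifts it by the CE length
    cds_start = model.cds_start
    if ce_tx[1] <= model.cds_start:
        cds_start += ce_e - ce_s
    return SplicedTranscript(seq=seq, cds_start=cds_start, ce_tx=ce_tx, junctions_tx=sorted(junctions))


def translate_with_ce(
    mrna: str | SplicedTranscript,
    cds_start: int | None = None,
    ce_tx: tuple[int, int] | None = None,
    reference_protein_length: int | None = None,
) -> ProteinProduct:
    """Translate from the start codon to the first stop; extract the cryptic peptide.

    A codon belongs to the CE iff its first base lies within ``ce_tx``
    (half-open, transcript coordinates) — unambiguous for codons spanning the
    CE boundary.  ``stop_in_ce`` is true iff the stop codon's first base lies
    in the CE.  ``truncated`` compares the product length with
    ``reference_protein_length`` when given.  If no stop codon occurs before
    the sequence end the product is flagged ``non_stop``.
    """
    if isinstance(mrna, SplicedTranscript):
        seq = mrna.seq
        cds_start = mrna.cds_start if cds_start is None else cds_start
        ce_tx = mrna.ce_tx if ce_tx is None else ce_tx
    else:
        seq = mrna
        if cds_start is None:
            raise ValueError("cds_start required when passing a raw sequence")
    if seq[cds_start : cds_start + 3] != "ATG":
        raise ValueError("cds_start does not point at an ATG")

    n_codons = (len(seq) - cds_start) // 3
    coding = seq[cds_start : cds_start + 3 * n_codons]
    aa = str(Seq(coding).translate())  # standard genetic code, '*' at stops
    stop_idx = aa.find("*")
    non_stop = stop_idx == -1
    protein = aa if non_stop else aa[:stop_idx]
    stop_tx_start = None if non_stop else cds_start + 3 * stop_idx

    in_ce = [False] * len(protein)
    if ce_tx is not None:
        for i in range(len(protein)):
            first = cds_start + 3 * i
            in_ce[i] = ce_tx[0] <= first < ce_tx[1]
    cryptic_suffix = "".join(r for r, flag in zip(protein, in_ce) if flag)
    stop_in_ce = (
        ce_tx is not None
        and stop_tx_start is not None
        and ce_tx[0] <= stop_tx_start < ce_tx[1]
    )
    truncated = (
        None
        if reference_protein_length is None
        else len(protein) < reference_protein_length
    )
    return ProteinProduct(
        protein=protein,
        cryptic_suffix=cryptic_suffix,
        stop_in_ce=bool(stop_in_ce),
        truncated=truncated,
        stop_tx_start=stop_tx_start,
        non_stop=non_stop,
    )


def flag_nmd(
    product: ProteinProduct,
    transcript: SplicedTranscript | Sequence[int],
    rule_nt: int = 50,
) -> bool:
    """50-nt rule: NMD candidate iff the stop codon lies > ``rule_nt``
    nucleotides upstream of the final exon-exon junction.

    Distance is counted from the base after the stop codon to the junction
    (strict >, so a stop exactly ``rule_nt`` nt upstream is not a candidate).
    A stop in the final exon (at or past the last junction) is never a
    candidate, nor is a non-stop product.  Sets ``product.nmd_candidate``.
    """
    junctions = (
        transcript.junctions_tx if isinstance(transcript, SplicedTranscript) else list(transcript)
    )
    if product.non_stop or product.stop_tx_start is None or not junctions:
        product.nmd_candidate = False
        return False
    last_junction = max(junctions)
    distance = last_junction - (product.stop_tx_start + 3)
    product.nmd_candidate = distance > rule_nt
    return product.nmd_candidate


def models_from_gtf(gtf_path: str | Path) -> dict[str, TranscriptModel]:
    """Load transcript models (exons + CDS transcript coordinates) from a GTF.

    Transcripts without CDS records are skipped (no reading frame to
    evaluate).  The returned ``cds_end`` is one past the last CDS base as
    recorded in the GTF.
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
    import collections

    tx_exons: dict[str, list[tuple[int, int]]] = collections.defaultdict(list)
    tx_cds: dict[str, list[tuple[int, int]]] = collections.defaultdict(list)
    meta: dict[str, tuple[str, str, str]] = {}
    for feat in db.all_features():
        if feat.featuretype not in ("exon", "CDS"):
            continue
        tid = feat.attributes["transcript_id"][0]
        gene = feat.attributes.get("gene_id", [tid])[0]
        meta.setdefault(tid, (feat.seqid, feat.strand, gene))
        (tx_exons if feat.featuretype == "exon" else tx_cds)[tid].append(
            (feat.start - 1, feat.end)
        )

    models: dict[str, TranscriptModel] = {}
    for tid, exons in tx_exons.items():
        cds = sorted(tx_cds.get(tid, []))
        if not cds:
            continue
        chrom, strand, gene = meta[tid]
        exons = sorted(exons)
        spans, total = _tx_coords(exons, strand)
        # genomic -> transcript coordinate; spans are in 5'->3' piece order
        ordered = exons if strand != "-" else exons[::-1]

        def to_tx(gpos: int) -> int:
            for (s, e), (ts, _te) in zip(ordered, spans):
                if s <= gpos < e:
                    return ts + (gpos - s) if strand != "-" else ts + (e - 1 - gpos)
            raise ValueError(f"position {gpos} not exonic in {tid}")

        if strand == "-":
            # 5' end is the genomic max CDS end, 3' end the genomic min start
            cds_start_tx = to_tx(cds[-1][1] - 1)
            cds_end_tx = to_tx(cds[0][0]) + 1
        else:
            cds_start_tx = to_tx(cds[0][0])
            cds_end_tx = to_tx(cds[-1][1] - 1) + 1
        models[tid] = TranscriptModel(
            gene_id=gene,
            transcript_id=tid,
            chrom=chrom,
            strand=strand,
            exons=exons,
            cds_start=cds_start_tx,
            cds_end=cds_end_tx,
        )
    return models


def read_fasta(path: str | Path) -> dict[str, str]:
    """Plain FASTA reader returning uppercase sequences keyed by record id."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
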