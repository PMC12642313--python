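"""Cryptic-splicing event calling against a transcript annotation.

A junction is called cryptic when (strict inequalities throughout):

* mean control Ψ < ``psi_control`` (default 0.05),
* ΔΨ (case − control, signed) > ``delta_psi`` (default 0.10), and
* the junction is absent from the annotated-junction set (exact coordinate
  and strand match).

Event classes follow which splice site is annotated: donor annotated only →
``cryptic_acceptor``; acceptor only → ``cryptic_donor``; neither →
``other_unannotated``.  Two cryptic junctions anchored at opposite ends of
the same annotated intron are paired into a ``cryptic_exon`` whose interval
is the gap between their interior ends.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
import pandas as pd

from .annotation import AnnotationIndex


class CrypticEvent(NamedTuple):
    chrom: str
    start: int
    end: int
    strand: str
    gene: str
    psi_control: float
    delta_psi: float
    event_class: str


def classify_events(
    psi_table: pd.DataFrame,
    index: AnnotationIndex,
    psi_control: float = 0.05,
    delta_psi: float = 0.10,
    signed: bool = True,
    control: str = "control",
) -> pd.DataFrame:
    """Apply the cryptic-splicing criteria to an aggregated Ψ table.

    ``psi_table`` comes from :func:`crypticflow.junctions.aggregate_delta_psi`
    (columns ``chrom,start,end,strand,mean_psi_<control>,delta_psi,excluded``).
    With ``signed=False`` the ΔΨ criterion uses \\|ΔΨ\\| instead of the signed
    inclusion gain.  Junctions undefined in all replicates of a condition are
    never called.  Returns the cryptic subset with ``event_class`` and host
    ``gene`` columns.
    """
    for t, name in ((psi_control, "psi_control"), (delta_psi, "delta_psi")):
        if not 0 < t < 1:
            raise ValueError(f"threshold {name}={t} outside (0, 1)")

    df = psi_table.copy()
    ctrl = df[f"mean_psi_{control}"]
    dpsi = df["delta_psi"] if signed else df["delta_psi"].abs()
    passes = (ctrl < psi_control) & (dpsi > delta_psi) & ~df["excluded"].astype(bool)
    passes &= ctrl.notna() & dpsi.notna()

    annotated = np.array(
        [
            index.has_junction(r.chrom, r.start, r.end, r.strand)
            for r in df.itertuples(index=False)
        ]
    ) if len(df) else np.array([], dtype=bool)
    cryptic = df.loc[passes.to_numpy() & ~annotated].copy()

    classes, genes, ambiguous = [], [], []
    for r in cryptic.itertuples(index=False):
        if r.strand == "-":
            donor_pos, acceptor_pos = r.end, r.start
        else:
            donor_pos, acceptor_pos = r.start, r.end
        donor_known = index.has_donor(r.chrom, donor_pos, r.strand)
        acceptor_known = index.has_acceptor(r.chrom, acceptor_pos, r.strand)
        if donor_known and not acceptor_known:
            classes.append("cryptic_acceptor")
        elif acceptor_known and not donor_known:
            classes.append("cryptic_donor")
        else:
            classes.append("other_unannotated")
        hit = index.genes_overlapping(r.chrom, r.start, r.end, r.strand)
        genes.append(";".join(sorted(hit)) if hit else "")
        ambiguous.append(r.strand not in "+-")
    cryptic["event_class"] = classes
    cryptic["gene"] = genes
    cryptic["strand_ambiguous"] = ambiguous
    cryptic["psi_control"] = cryptic[f"mean_psi_{control}"]
    return cryptic.reset_index(drop=True)


def pair_cryptic_exon(events: pd.DataFrame, index: AnnotationIndex) -> pd.DataFrame:
    """Pair cryptic junctions that flank a cassette inside one annotated intron.

    The genomic-left junction must start at the intron's left boundary and end
    inside it; the genomic-right junction must end at the intron's right
    boundary and start inside it (donor/acceptor roles swap with strand, the
    geometry does not).  The cryptic-exon interval is
    ``[left.end, right.start)``; zero-width cassettes are rejected as
    degenerate.  Junction pairs resolving to different genes or strands are
    never paired.  Returns one row per cryptic exon.
    """
    rows = []
    if events.empty:
        return pd.DataFrame(
            columns=["chrom", "ce_start", "ce_end", "ce_length", "strand", "gene",
                     "intron_start", "intron_end", "left_junction", "right_junction"]
        )
    for key, grp in events.groupby(["chrom", "strand"]):
        chrom, strand = key
        # bucket cryptic junctions by the annotated intron containing them
        by_intron: dict[tuple[int, int, str], dict[str, list]] = {}
        for r in grp.itertuples(index=False):
            for intron in index.introns_containing(chrom, r.start, r.end, strand):
                bucket = by_intron.setdefault(
                    (intron.start, intron.end, intron.gene_id), {"left": [], "right": []}
                )
                if r.start == intron.start and r.end < intron.end:
                    bucket["left"].append(r)
                elif r.end == intron.end and r.start > intron.start:
                    bucket["right"].append(r)
        for (istart, iend, gene), bucket in by_intron.items():
            for lj in bucket["left"]:
                for rj in bucket["right"]:
                    ce_start, ce_end = lj.end, rj.start
                    if ce_end - ce_start <= 0:
                        continue  # degenerate: empty cassette
                    rows.append(
                        {
                            "chrom": chrom,
                            "ce_start": ce_start,
                            "ce_end": ce_end,
                            "ce_length": ce_end - ce_start,
                            "strand": strand,
                            "gene": gene,
                            "intron_start": istart,
                            "intron_end": iend,
                            "left_junction": f"{chrom}:{lj.start}-{lj.end}",
                            "right_junction": f"{chrom}:{rj.start}-{rj.end}",
                        }
                    )
    return pd.DataFrame(rows)


def write_events(events: pd.DataFrame, path) -> None:
    events.to_csv(path, sep="\t", index=False)


def write_ce_bed(ces: pd.DataFrame, path) -> None:
    """Cryptic-exon intervals as 6-column BED (0-based half-open)."""
    if ces.empty:
        pd.DataFrame(columns=range(6)).to_csv(path, sep="\t", header=False, index=False)
        return
    bed = pd.DataFrame(
        {
            "chrom": ces["chrom"],
            "start": ces["ce_start"],
            "end": ces["ce_end"],
            "name": ces["gene"].fillna("") + "_CE",
            "score": 0,
            "strand": ces["strand"],
        }
    )
    bed.to_csv(path, sep="\t", header=False, index=False)
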