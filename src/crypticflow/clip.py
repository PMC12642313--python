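"""CLIP-seq peak enrichment statistics.

Fold enrichment for a peak is the ratio of library-size-normalised read
counts, (k1/n1)/(k2/n2) — IP over size-matched input, or IP of one condition
over another.  The p-value comes from the 2×2 table
``[[k1, n1-k1], [k2, n2-k2]]`` by Yates'-corrected χ², switching to the
two-sided Fisher exact test whenever any observed or expected cell is below
5.  Peaks are annotated by a priority hierarchy over overlapped features:
CDS > 5'UTR > 3'UTR > protein-coding intron > non-coding exon > non-coding
intron > intergenic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats
from scipy.stats.contingency import expected_freq

from .annotation import ANNOTATION_PRIORITY, AnnotationIndex

_MIN_P = 5e-324  # smallest positive float; keeps p in (0, 1]


@dataclass
class PeakEnrichment:
    fold_enrichment: float  # inf when k2=0<k1; nan when k1=k2=0
    p_value: float
    test_used: str  # "yates_chi2" | "fisher"
    direction: str  # "up" | "down" | "unchanged"
    k1: int
    n1: int
    k2: int
    n2: int
    annotation: str | None = None


def fisher_two_sided(k1: int, n1: int, k2: int, n2: int) -> float:
    """Two-sided Fisher exact p for the table [[k1, n1-k1], [k2, n2-k2]]."""
    return float(stats.fisher_exact([[k1, n1 - k1], [k2, n2 - k2]], alternative="two-sided")[1])


def needs_fisher(k1: int, n1: int, k2: int, n2: int, min_count: float = 5.0) -> bool:
    """True when any observed or expected cell of the 2×2 table is < ``min_count``."""
    obs = np.array([[k1, n1 - k1], [k2, n2 - k2]], dtype=float)
    if (obs < min_count).any():
        return True
    return bool((expected_freq(obs) < min_count).any())


def enrichment_test(k1: int, n1: int, k2: int, n2: int) -> PeakEnrichment:
    """Normalised fold enrichment and switchover p-value for one peak.

    ``k1``/``n1``: reads in the peak and total reads of the foreground
    library (IP); ``k2``/``n2``: same for the comparison library (input, or
    the other condition's IP).  Totals are post-deduplication library sizes.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library totals must be positive")
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2):
        raise ValueError("peak counts must satisfy 0 <= k <= n")

    if k1 == 0 and k2 == 0:
        fold = math.nan
    elif k2 == 0:
        fold = math.inf
    else:
        fold = (k1 / n1) / (k2 / n2)

    if needs_fisher(k1, n1, k2, n2):
        p = fisher_two_sided(k1, n1, k2, n2)
        test = "fisher"
    else:
        chi2 = stats.chi2_contingency(
            [[k1, n1 - k1], [k2, n2 - k2]], correction=True
        )
        p = float(chi2.pvalue)
        test = "yates_chi2"
    p = min(max(p, _MIN_P), 1.0)

    if math.isnan(fold) or fold == 1.0:
        direction = "unchanged"
    else:
        direction = "up" if fold > 1.0 else "down"
    return PeakEnrichment(fold, p, test, direction, k1, n1, k2, n2)


def enrichment_table(
    peaks: pd.DataFrame,
    k_col: str,
    n1: int,
    k2_col: str,
    n2: int,
    fdr: bool = False,
) -> pd.DataFrame:
    """Vector form of :func:`enrichment_test` over a peak count table.

    Benjamini–Hochberg FDR is offered as an optional ``padj`` column and off
    by default (the analysis this mirrors reports raw p-values).
    """
    recs = [
        enrichment_test(int(k1), n1, int(k2), n2)
        for k1, k2 in zip(peaks[k_col], peaks[k2_col])
    ]
    out = peaks.copy()
    out["fold_enrichment"] = [r.fold_enrichment for r in recs]
    out["p_value"] = [r.p_value for r in recs]
    out["test_used"] = [r.test_used for r in recs]
    out["direction"] = [r.direction for r in recs]
    if fdr:
        out["padj"] = stats.false_discovery_control(out["p_value"].to_numpy())
    return out


def count_reads_in_peaks(peaks: pd.DataFrame, reads: pd.DataFrame) -> pd.DataFrame:
    """Count reads overlapping each peak (strand-aware, ≥1 bp overlap).

    ``peaks``: columns ``peak_id, chrom, start, end, strand``; ``reads``:
    columns ``chrom, start, end, strand`` plus optional ``sample``.  A read is
    counted once per peak per sample.  Returns the peak table with one
    ``reads_<sample>`` column per sample (``reads_all`` if unlabelled) and the
    per-sample totals in ``DataFrame.attrs['total_reads']``.
    """
    samples = sorted(reads["sample"].unique()) if "sample" in reads else ["all"]
    out = peaks.copy()
    totals = {}
    for s in samples:
        sub = reads if s == "all" else reads[reads["sample"] == s]
        totals[s] = int(len(sub))
        trees: dict[tuple[str, str], IntervalTree] = {}
        for key, grp in sub.groupby(["chrom", "strand"]):
            tree = IntervalTree()
            for r in grp.itertuples(index=False):
                tree.addi(r.start, r.end)
            trees[key] = tree
        counts = []
        for p in peaks.itertuples(index=False):
            tree = trees.get((p.chrom, p.strand))
            counts.append(len(tree.overlap(p.start, p.end)) if tree is not None else 0)
        out[f"reads_{s}"] = counts
    out.attrs["total_reads"] = totals
    return out


def annotate_peak(
    index: AnnotationIndex, chrom: str, start: int, end: int, strand: str
) -> str:
    """Highest-priority annotation category overlapped by the peak."""
    strands = [strand] if strand in "+-" else ["+", "-"]
    for cat in ANNOTATION_PRIORITY:
        for s in strands:
            feats = index.features.get((chrom, s))
            if feats is not None and feats[cat].overlap(start, end):
                return cat
    return "intergenic"


def annotate_peaks(index: AnnotationIndex, peaks: pd.DataFrame) -> pd.DataFrame:
    out = peaks.copy()
    out["annotation"] = [
        annotate_peak(index, p.chrom, p.start, p.end, p.strand)
        for p in peaks.itertuples(index=False)
    ]
    return out


@dataclass
class BindingOverlap:
    """Set algebra over genes bound in two conditions."""

    size_a: int
    size_b: int
    a_only: int
    b_only: int
    shared: int
    union: int

    def __post_init__(self) -> None:
        if self.union != self.a_only + self.b_only + self.shared:
            raise ValueError("union must equal a_only + b_only + shared")
        if self.size_a != self.a_only + self.shared or self.size_b != self.b_only + self.shared:
            raise ValueError("set sizes inconsistent with exclusive/shared counts")

    def fraction_of_union(self, part: str) -> float:
        """Fraction of the union in ``part`` ∈ {a_only, b_only, shared}, as a percentage."""
        return 100.0 * getattr(self, part) / self.union if self.union else 0.0

    @classmethod
    def from_sets(cls, genes_a, genes_b) -> "BindingOverlap":
        a, b = set(genes_a), set(genes_b)
        shared = len(a & b)
        return cls(len(a), len(b), len(a - b), len(b - a), shared, len(a | b))

    @classmethod
    def from_counts(cls, size_a: int, size_b: int, a_only: int, b_only: int) -> "BindingOverlap":
        """Solve shared and union from set sizes and exclusive counts."""
        shared = size_a - a_only
        if shared != size_b - b_only:
            raise ValueError(
                f"inconsistent counts: size_a - a_only = {shared} but "
                f"size_b - b_only = {size_b - b_only}"
            )
        return cls(size_a, size_b, a_only, b_only, shared, a_only + b_only + shared)


def binding_overlap(genes_a, genes_b) -> BindingOverlap:
    """Overlap summary of two bound-gene sets (exact set algebra)."""
    return BindingOverlap.from_sets(genes_a, genes_b)
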