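"""Threshold-based expression analyses: single-cell QC, DEG presets,
signature definition and scoring, quadrant overlap, inhibitor-rescue calls.

Cell matrices travel as :class:`anndata.AnnData` (cells × genes); DE tables
as DataFrames with columns ``gene, log2fc, padj`` and, where relevant,
``pct`` (fraction of cells expressing) or ``fold_change`` (linear).

Boundary conventions follow the printed criteria exactly: genes kept when
expressed in *more than* ``min_cells_per_gene`` cells; cells dropped when
detected genes < ``min_genes_per_cell`` or mitochondrial fraction ≥
``max_mito_frac``; bulk DEGs need padj < 0.05 and |log2FC| > 1 (strict);
cluster markers need padj < 0.05, pct ≥ 10% and log2FC ≥ 1 (inclusive);
signature genes need pct ≥ 20%, padj < 0.05 and linear fold change ≥ 4.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd

DEG_PRESETS = {
    # name: (padj_max, log2fc threshold, log2fc comparison, min pct, use |log2fc|)
    "bulk": dict(padj_max=0.05, lfc=1.0, inclusive=False, min_pct=0.0, absolute=True),
    "marker": dict(padj_max=0.05, lfc=1.0, inclusive=True, min_pct=0.10, absolute=False),
}


def _dense(X) -> np.ndarray:
    return np.asarray(X.todense()) if hasattr(X, "todense") else np.asarray(X)


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def qc_filter(
    adata: ad.AnnData,
    min_cells_per_gene: int = 5,
    min_genes_per_cell: int = 200,
    max_mito_frac: float = 0.10,
) -> tuple[ad.AnnData, dict]:
    """Gene-then-cell quality filter on a counts AnnData.

    Requires a boolean ``adata.var['mito']`` column (genes counted toward the
    mitochondrial fraction).  Keeps genes expressed (count > 0) in more than
    ``min_cells_per_gene`` cells; then keeps cells with at least
    ``min_genes_per_cell`` detected genes and mitochondrial fraction strictly
    below ``max_mito_frac``.  Returns the filtered copy and a report of what
    each step removed.  Raises if no cell survives.
    """
    if "mito" not in adata.var:
        raise ValueError("adata.var['mito'] boolean flag is required")
    X = _dense(adata.X)
    n_cells0, n_genes0 = adata.shape

    cells_per_gene = (X > 0).sum(axis=0)
    gene_keep = cells_per_gene > min_cells_per_gene  # strict: "more than 5 cells"
    X = X[:, gene_keep]
    sub = adata[:, gene_keep]

    detected = (X > 0).sum(axis=1)
    total = X.sum(axis=1)
    mito_mask = sub.var["mito"].to_numpy().astype(bool)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(total > 0, X[:, mito_mask].sum(axis=1) / np.maximum(total, 1), 0.0)
    cell_keep = (detected >= min_genes_per_cell) & (mito_frac < max_mito_frac)

    report = {
        "genes_in": int(n_genes0),
        "genes_removed": int(n_genes0 - gene_keep.sum()),
        "cells_in": int(n_cells0),
        "cells_removed_low_genes": int((detected < min_genes_per_cell).sum()),
        "cells_removed_high_mito": int(
            ((detected >= min_genes_per_cell) & (mito_frac >= max_mito_frac)).sum()
        ),
        "cells_out": int(cell_keep.sum()),
        "genes_out": int(gene_keep.sum()),
    }
    if report["cells_out"] == 0:
        raise ValueError(f"QC removed every cell; report: {report}")
    return sub[cell_keep].copy(), report


# ---------------------------------------------------------------------------
# DEG thresholds
# ---------------------------------------------------------------------------

def threshold_deg(
    records: pd.DataFrame,
    preset: str = "bulk",
    padj_max: float | None = None,
    lfc: float | None = None,
    min_pct: float | None = None,
) -> pd.DataFrame:
    """Filter a DE table to significant genes under a named preset.

    ``bulk``: padj < 0.05 and \\|log2FC\\| > 1 (strict).  ``marker``: padj <
    0.05, pct ≥ 0.10 and log2FC ≥ 1 (inclusive, up-regulated only).
    Explicit keyword arguments override the preset values.  Adds a
    ``direction`` column from the sign of log2FC.
    """
    if preset not in DEG_PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(DEG_PRESETS)}")
    p = dict(DEG_PRESETS[preset])
    if padj_max is not None:
        p["padj_max"] = padj_max
    if lfc is not None:
        p["lfc"] = lfc
    if min_pct is not None:
        p["min_pct"] = min_pct

    lfc_val = records["log2fc"].abs() if p["absolute"] else records["log2fc"]
    lfc_ok = lfc_val >= p["lfc"] if p["inclusive"] else lfc_val > p["lfc"]
    keep = (records["padj"] < p["padj_max"]) & lfc_ok
    if p["min_pct"] > 0:
        if "pct" not in records:
            raise ValueError("preset requires a 'pct' column")
        keep &= records["pct"] >= p["min_pct"]
    out = records.loc[keep].copy()
    out["direction"] = np.where(out["log2fc"] > 0, "up", "down")
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Signature definition and scoring
# ---------------------------------------------------------------------------

def define_signature(
    records: pd.DataFrame,
    min_pct: float = 0.20,
    padj_max: float = 0.05,
    min_fc: float = 4.0,
    fc_scale: str = "linear",
) -> list[str]:
    """Signature genes for a target population from its marker statistics.

    A gene joins the signature iff it is expressed in ≥ ``min_pct`` of the
    population, padj < ``padj_max`` and fold change ≥ ``min_fc``.  The fold
    change is linear by default (``fold_change`` column, or ``2**log2fc``);
    ``fc_scale='log2'`` applies ``min_fc`` to log2fc directly.
    """
    if "fold_change" in records:
        fc = records["fold_change"]
    elif "log2fc" in records:
        fc = records["log2fc"] if fc_scale == "log2" else 2.0 ** records["log2fc"]
    else:
        raise ValueError("need a 'fold_change' or 'log2fc' column")
    keep = (records["pct"] >= min_pct) & (records["padj"] < padj_max) & (fc >= min_fc)
    genes = records.loc[keep, "gene"].tolist()
    if not genes:
        warnings.warn("signature definition selected no genes", stacklevel=2)
    return genes


def score_signature(
    adata: ad.AnnData,
    signature: list[str],
    normalize: bool = True,
    target_sum: float = 1e4,
) -> pd.Series:
    """Per-cell signature score: mean expression over the signature genes.

    By default counts are library-size normalised to ``target_sum`` and
    log1p-transformed first, matching scoring on processed single-cell data;
    ``normalize=False`` scores raw values.  Signature genes absent from the
    matrix are reported (warning) and dropped; an empty intersection raises.
    """
    present = [g for g in signature if g in adata.var_names]
    missing = sorted(set(signature) - set(present))
    if missing:
        warnings.warn(f"{len(missing)} signature genes not in matrix: {missing[:5]}...", stacklevel=2)
    if not present:
        raise ValueError("no signature gene present in the matrix")
    X = _dense(adata.X).astype(float)
    if normalize:
        lib = X.sum(axis=1, keepdims=True)
        X = np.log1p(np.where(lib > 0, X / np.maximum(lib, 1) * target_sum, 0.0))
    cols = [adata.var_names.get_loc(g) for g in present]
    return pd.Series(X[:, cols].mean(axis=1), index=adata.obs_names, name="signature_score")


# ---------------------------------------------------------------------------
# Quadrant overlap and rescue
# ---------------------------------------------------------------------------

@dataclass
class QuadrantResult:
    table: pd.DataFrame  # per-gene quadrant assignment
    counts: dict  # quadrant -> n genes
    overlap: dict  # overlap percentages relative to each axis's DE sets


def quadrant_analysis(
    deg_a: pd.DataFrame,
    deg_b: pd.DataFrame,
    preset_a: str = "bulk",
    preset_b: str = "bulk",
) -> QuadrantResult:
    """Joint direction-of-change classification of two DE comparisons.

    Q1 = up in both, Q2 = up in B only, Q3 = down in both, Q4 = down in B
    only (genes significant on both axes but discordant land in Q2/Q4 by the
    B direction); genes significant on neither or one axis are ``none``.
    Overlap percentages report, for each axis, what fraction of its up/down
    set is shared with the other axis's same-direction set.
    """
    genes_a, genes_b = set(deg_a["gene"]), set(deg_b["gene"])
    if not genes_a & genes_b:
        raise ValueError("DE tables share no genes")
    sig_a = threshold_deg(deg_a, preset=preset_a)
    sig_b = threshold_deg(deg_b, preset=preset_b)
    dir_a = dict(zip(sig_a["gene"], sig_a["direction"]))
    dir_b = dict(zip(sig_b["gene"], sig_b["direction"]))

    rows = []
    for gene in sorted(genes_a | genes_b):
        da, db = dir_a.get(gene), dir_b.get(gene)
        if da == "up" and db == "up":
            quad = "Q1"
        elif da == "down" and db == "down":
            quad = "Q3"
        elif db == "up" and da == "down":
            quad = "Q2"
        elif db == "down" and da == "up":
            quad = "Q4"
        else:
            quad = "none"
        rows.append((gene, da or "", db or "", quad))
    table = pd.DataFrame(rows, columns=["gene", "direction_a", "direction_b", "quadrant"])
    counts = table["quadrant"].value_counts().to_dict()
    for q in ("Q1", "Q2", "Q3", "Q4", "none"):
        counts.setdefault(q, 0)

    def pct(shared: int, total: int) -> float:
        return 100.0 * shared / total if total else 0.0

    up_a = {g for g, d in dir_a.items() if d == "up"}
    dn_a = {g for g, d in dir_a.items() if d == "down"}
    up_b = {g for g, d in dir_b.items() if d == "up"}
    dn_b = {g for g, d in dir_b.items() if d == "down"}
    overlap = {
        "up_shared": len(up_a & up_b),
        "down_shared": len(dn_a & dn_b),
        "pct_of_a_up": pct(len(up_a & up_b), len(up_a)),
        "pct_of_b_up": pct(len(up_a & up_b), len(up_b)),
        "pct_of_a_down": pct(len(dn_a & dn_b), len(dn_a)),
        "pct_of_b_down": pct(len(dn_a & dn_b), len(dn_b)),
    }
    return QuadrantResult(table=table, counts=counts, overlap=overlap)


def classify_rescue(
    deg_untreated: pd.DataFrame,
    deg_treated: pd.DataFrame,
    p_max: float = 0.05,
    absolute: bool = True,
) -> pd.DataFrame:
    """Per-gene rescue flag for an inhibitor-treatment contrast.

    A gene is rescued iff its fold change under treatment is smaller than
    without treatment (|log2FC| by default, raw signed log2FC with
    ``absolute=False``; strict <) and the untreated contrast has p (or padj)
    < ``p_max``.  Genes missing from either table are left unclassified
    (``rescued`` = NA).
    """
    pcol = "padj" if "padj" in deg_untreated else "pvalue"
    merged = deg_untreated[["gene", "log2fc", pcol]].merge(
        deg_treated[["gene", "log2fc"]], on="gene", how="outer",
        suffixes=("_untreated", "_treated"),
    )
    u = merged["log2fc_untreated"]
    t = merged["log2fc_treated"]
    if absolute:
        u, t = u.abs(), t.abs()
    rescued = (t < u) & (merged[pcol] < p_max)
    rescued = rescued.astype("boolean")
    rescued[merged["log2fc_untreated"].isna() | merged["log2fc_treated"].isna()] = pd.NA
    merged["rescued"] = rescued
    return merged
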