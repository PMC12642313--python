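"""Junction count parsing and percent-spliced-in (Ψ) quantification.

Ψ for a junction *j* in a sample is the fraction of junction-spanning reads
supporting *j* among its *competing set*: all junctions sharing *j*'s donor
site or *j*'s acceptor site (union, including *j* itself).  ΔΨ is the
difference of condition means (case − control) computed over replicates where
Ψ is defined.  A zero denominator leaves Ψ undefined (NaN), which is distinct
from Ψ = 0.

Coordinates are handled internally as 0-based half-open; the STAR
``SJ.out.tab`` dialect (1-based inclusive intron) is converted on read/write.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Literal, Mapping

import numpy as np
import pandas as pd

JUNCTION_KEY = ["chrom", "start", "end", "strand"]

_STAR_STRAND = {0: ".", 1: "+", 2: "-"}
_STAR_STRAND_INV = {".": 0, "+": 1, "-": 2}

Dialect = Literal["star_sj", "junction_tsv"]
PsiMode = Literal["union", "donor", "acceptor"]


def read_junction_table(
    path: str | Path, dialect: Dialect = "star_sj", sample: str | None = None
) -> pd.DataFrame:
    """Read a junction count table into a long DataFrame.

    Returns columns ``chrom, start, end, strand, reads[, sample]`` with
    0-based half-open intron coordinates.  ``star_sj`` is the 9-column STAR
    ``SJ.out.tab`` dialect (1-based inclusive intron, strand coded 0/1/2,
    column 7 = uniquely-mapping reads, which is what Ψ uses);
    ``junction_tsv`` is a headered TSV with columns
    ``chrom, start, end, strand, reads[, sample]`` already 0-based half-open.

    Malformed lines raise ``ValueError`` naming the offending line numbers.
    """
    path = Path(path)
    if dialect == "star_sj":
        rows, bad = [], []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                parts = line.rstrip("\n").split("\t")
                try:
                    chrom = parts[0]
                    start1, end1 = int(parts[1]), int(parts[2])
                    strand = _STAR_STRAND[int(parts[3])]
                    reads = int(parts[6])
                    if reads < 0 or start1 - 1 >= end1:
                        raise ValueError
                    rows.append((chrom, start1 - 1, end1, strand, reads))
                except (IndexError, ValueError, KeyError):
                    bad.append(lineno)
        if bad:
            raise ValueError(f"{path}: malformed SJ.out.tab lines: {bad}")
        df = pd.DataFrame(rows, columns=JUNCTION_KEY + ["reads"])
    elif dialect == "junction_tsv":
        df = pd.read_csv(path, sep="\t")
        missing = set(JUNCTION_KEY + ["reads"]) - set(df.columns)
        if missing:
            raise ValueError(f"{path}: junction_tsv missing columns {sorted(missing)}")
        if (df["reads"] < 0).any():
            bad = (df.index[df["reads"] < 0] + 2).tolist()  # +2: header + 1-based
            raise ValueError(f"{path}: negative read counts on lines {bad}")
        if (df["start"] >= df["end"]).any():
            bad = (df.index[df["start"] >= df["end"]] + 2).tolist()
            raise ValueError(f"{path}: start >= end on lines {bad}")
    else:
        raise ValueError(f"unknown junction table dialect: {dialect!r}")

    if df.empty:
        warnings.warn(f"{path}: empty junction table", stacklevel=2)
    if sample is not None:
        df["sample"] = sample
    return df


def write_junction_table(
    df: pd.DataFrame, path: str | Path, dialect: Dialect = "star_sj"
) -> None:
    """Write a long junction table; inverse of :func:`read_junction_table`."""
    path = Path(path)
    if dialect == "star_sj":
        out = pd.DataFrame(
            {
                "chrom": df["chrom"],
                "start": df["start"] + 1,
                "end": df["end"],
                "strand": df["strand"].map(_STAR_STRAND_INV),
                "motif": 1,  # GT/AG
                "annotated": 0,
                "unique": df["reads"],
                "multi": 0,
                "overhang": 50,
            }
        )
        out.to_csv(path, sep="\t", header=False, index=False)
    elif dialect == "junction_tsv":
        cols = JUNCTION_KEY + ["reads"] + (["sample"] if "sample" in df else [])
        df[cols].to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown junction table dialect: {dialect!r}")


def compute_psi(counts: pd.DataFrame, mode: PsiMode = "union") -> pd.DataFrame:
    """Per-junction Ψ for one sample.

    ``counts`` holds one row per junction (columns ``chrom, start, end,
    strand, reads``).  The denominator is the read total over the competing
    set; with ``mode='union'`` that is every junction sharing the start *or*
    the end coordinate (on the same chromosome/strand), with ``'donor'`` /
    ``'acceptor'`` only one side is shared.  Adds columns ``denominator`` and
    ``psi`` (NaN when the denominator is zero; a junction with no competitor
    and reads > 0 has Ψ = 1).
    """
    df = counts.copy()
    start_tot = df.groupby(["chrom", "strand", "start"])["reads"].transform("sum")
    end_tot = df.groupby(["chrom", "strand", "end"])["reads"].transform("sum")
    if mode == "union":
        denom = start_tot + end_tot - df["reads"]
    elif mode == "donor":
        denom = np.where(df["strand"] == "-", end_tot, start_tot)
    elif mode == "acceptor":
        denom = np.where(df["strand"] == "-", start_tot, end_tot)
    else:
        raise ValueError(f"unknown psi mode: {mode!r}")
    denom = pd.Series(np.asarray(denom), index=df.index)
    df["denominator"] = denom
    with np.errstate(invalid="ignore"):
        df["psi"] = np.where(denom > 0, df["reads"] / denom.replace(0, np.nan), np.nan)
    return df


def psi_matrix(
    counts: pd.DataFrame, samples: list[str] | None = None, mode: PsiMode = "union"
) -> pd.DataFrame:
    """Ψ per junction and sample over the union of observed junctions.

    ``counts`` is long-form with a ``sample`` column.  A junction absent from
    one sample's table contributes 0 reads there, so its Ψ is 0 when
    competitors were observed and NaN when the whole competing set is silent.
    Returns a wide frame keyed by junction with ``psi_<sample>`` and
    ``reads_<sample>`` columns.
    """
    if "sample" not in counts.columns:
        raise ValueError("psi_matrix needs a 'sample' column")
    samples = samples or sorted(counts["sample"].unique())
    wide = (
        counts.pivot_table(
            index=JUNCTION_KEY, columns="sample", values="reads", aggfunc="sum", fill_value=0
        )
        .reindex(columns=samples, fill_value=0)
        .reset_index()
    )
    out = wide[JUNCTION_KEY].copy()
    out.insert(
        0,
        "junction_id",
        wide["chrom"].astype(str)
        + ":"
        + wide["start"].astype(str)
        + "-"
        + wide["end"].astype(str)
        + ":"
        + wide["strand"].astype(str),
    )
    for s in samples:
        per = wide[JUNCTION_KEY].assign(reads=wide[s])
        psi = compute_psi(per, mode=mode)
        out[f"reads_{s}"] = psi["reads"].to_numpy()
        out[f"psi_{s}"] = psi["psi"].to_numpy()
    return out


def aggregate_delta_psi(
    psi_wide: pd.DataFrame,
    condition_map: Mapping[str, str],
    control: str = "control",
    case: str = "case",
) -> pd.DataFrame:
    """Condition-mean Ψ and ΔΨ = mean(case) − mean(control).

    Means are taken over replicates where Ψ is defined; a junction undefined
    in every replicate of a condition gets a NaN mean (and NaN ΔΨ) and is
    flagged ``excluded`` for downstream classification.
    """
    labels = set(condition_map.values())
    if labels != {control, case}:
        raise ValueError(f"condition map must cover exactly {{{control}, {case}}}, got {labels}")
    by_cond: dict[str, list[str]] = {control: [], case: []}
    for sample, cond in condition_map.items():
        if f"psi_{sample}" not in psi_wide.columns:
            raise ValueError(f"no psi column for sample {sample!r}")
        by_cond[cond].append(sample)
    for cond, ss in by_cond.items():
        if not ss:
            raise ValueError(f"condition {cond!r} has zero samples")

    out = psi_wide.copy()
    for cond, ss in by_cond.items():
        block = out[[f"psi_{s}" for s in ss]]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            out[f"mean_psi_{cond}"] = block.mean(axis=1, skipna=True)
        out[f"n_defined_{cond}"] = block.notna().sum(axis=1)
    out["delta_psi"] = out[f"mean_psi_{case}"] - out[f"mean_psi_{control}"]
    out["excluded"] = (out[f"n_defined_{control}"] == 0) | (out[f"n_defined_{case}"] == 0)
    return out


def psi_table(
    counts: pd.DataFrame,
    condition_map: Mapping[str, str],
    control: str = "control",
    case: str = "case",
    mode: PsiMode = "union",
) -> pd.DataFrame:
    """Convenience composite: :func:`psi_matrix` then :func:`aggregate_delta_psi`."""
    wide = psi_matrix(counts, samples=sorted(condition_map), mode=mode)
    return aggregate_delta_psi(wide, condition_map, control=control, case=case)
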