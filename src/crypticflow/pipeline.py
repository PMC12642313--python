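"""End-to-end orchestration: config validation, staged execution, run manifest.

A pipeline run executes any subset of three stages from one declarative YAML
config: ``splice`` (junction tables → Ψ/ΔΨ → cryptic events → cryptic exons →
protein consequence when a genome is given), ``clip`` (peak counts →
enrichment statistics → annotation), and ``score`` (cell matrix → QC →
signature score).  Every output is a TSV under the configured output
directory, and a ``manifest.json`` records the package version, thresholds,
seed and SHA-256 checksums of all inputs, so a rerun with the same config is
byte-identical on deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__, annotation, clip, consequence, cryptic, expression, junctions


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    outdir: Path
    seed: int = 0
    splice: dict[str, Any] | None = None
    clip: dict[str, Any] | None = None
    score: dict[str, Any] | None = None
    raw: dict[str, Any] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw, base=Path(path).parent)

    @classmethod
    def from_dict(cls, raw: dict[str, Any], base: Path | None = None) -> "PipelineConfig":
        base = base or Path.cwd()
        if "outdir" not in raw:
            raise ConfigError("config needs an 'outdir'")
        cfg = cls(
            outdir=Path(raw["outdir"]),
            seed=int(raw.get("seed", 0)),
            splice=raw.get("splice"),
            clip=raw.get("clip"),
            score=raw.get("score"),
            raw=raw,
        )
        cfg.validate()
        return cfg

    def _paths(self) -> list[Path]:
        paths = []
        if self.splice:
            paths += [Path(s["path"]) for s in self.splice.get("samples", [])]
            if "gtf" in self.splice:
                paths.append(Path(self.splice["gtf"]))
            if "fasta" in self.splice:
                paths.append(Path(self.splice["fasta"]))
        if self.clip:
            paths.append(Path(self.clip["counts"]))
            if "gtf" in self.clip:
                paths.append(Path(self.clip["gtf"]))
        if self.score:
            paths.append(Path(self.score["matrix"]))
        return paths

    def validate(self) -> None:
        if not (self.splice or self.clip or self.score):
            raise ConfigError("config enables no stage")
        if self.splice:
            if "gtf" not in self.splice:
                raise ConfigError("splice stage needs a 'gtf'")
            if not self.splice.get("samples"):
                raise ConfigError("splice stage needs 'samples' entries")
            for thr in ("psi_control", "delta_psi"):
                v = self.splice.get(thr)
                if v is not None and not 0 < float(v) < 1:
                    raise ConfigError(f"splice.{thr}={v} outside (0, 1)")
        missing = [str(p) for p in self._paths() if not p.exists()]
        if missing:
            raise ConfigError(f"missing input files: {missing}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute the configured stages; return (and write) the run manifest."""
    config.validate()
    outdir = config.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "crypticflow_version": __version__,
        "seed": config.seed,
        "config": config.raw,
        "inputs": {str(p): _sha256(p) for p in config._paths()},
        "outputs": [],
        "stages": [],
    }

    def emit(df: pd.DataFrame, name: str) -> None:
        path = outdir / name
        df.to_csv(path, sep="\t", index=False)
        manifest["outputs"].append(name)

    stage = None
    try:
        for stage, runner, enabled in (
            ("splice", _run_splice, config.splice),
            ("clip", _run_clip, config.clip),
            ("score", _run_score, config.score),
        ):
            if enabled:
                runner(config, emit)
                manifest["stages"].append(stage)
    except Exception as exc:  # halt, naming the failing stage; partial outputs retained
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return manifest


def _run_splice(config: PipelineConfig, emit) -> None:
    sp = config.splice
    counts = pd.concat(
        [
            junctions.read_junction_table(
                s["path"], dialect=s.get("dialect", "star_sj"), sample=s["sample"]
            )
            for s in sp["samples"]
        ],
        ignore_index=True,
    )
    condition_map = {s["sample"]: s["condition"] for s in sp["samples"]}
    table = junctions.psi_table(counts, condition_map, mode=sp.get("psi_mode", "union"))
    emit(table, "psi_table.tsv")

    index = annotation.build_annotation_index(sp["gtf"])
    events = cryptic.classify_events(
        table,
        index,
        psi_control=float(sp.get("psi_control", 0.05)),
        delta_psi=float(sp.get("delta_psi", 0.10)),
        signed=bool(sp.get("signed", True)),
    )
    emit(events, "cryptic_events.tsv")
    ces = cryptic.pair_cryptic_exon(events, index)
    emit(ces, "cryptic_exons.tsv")
    cryptic.write_ce_bed(ces, config.outdir / "cryptic_exons.bed")

    if "fasta" in sp and not ces.empty:
        genome = consequence.read_fasta(sp["fasta"])
        models = consequence.models_from_gtf(sp["gtf"])
        by_gene: dict[str, consequence.TranscriptModel] = {}
        for m in models.values():
            by_gene.setdefault(m.gene_id, m)
        rows = []
        for r in ces.itertuples(index=False):
            model = by_gene.get(r.gene)
            if model is None:
                continue
            ref = consequence.translate_with_ce(consequence.mature_mrna(model, genome))
            spliced = consequence.splice_in_ce(model, (r.ce_start, r.ce_end), genome)
            product = consequence.translate_with_ce(
                spliced, reference_protein_length=len(ref.protein)
            )
            consequence.flag_nmd(product, spliced)
            rows.append(
                {
                    "gene": model.gene_id,
                    "transcript": model.transcript_id,
                    "ce_start": r.ce_start,
                    "ce_end": r.ce_end,
                    "product_length": product.length,
                    "cryptic_suffix": product.cryptic_suffix,
                    "stop_in_ce": product.stop_in_ce,
                    "truncated": product.truncated,
                    "nmd_candidate": product.nmd_candidate,
                }
            )
        emit(pd.DataFrame(rows), "ce_consequences.tsv")


def _run_clip(config: PipelineConfig, emit) -> None:
    cl = config.clip
    df = pd.read_csv(cl["counts"], sep="\t")
    n1 = int(df["total_ip"].iloc[0]) if "total_ip" in df else int(cl["total_ip"])
    n2 = int(df["total_input"].iloc[0]) if "total_input" in df else int(cl["total_input"])
    out = clip.enrichment_table(
        df, "reads_ip", n1, "reads_input", n2, fdr=bool(cl.get("fdr", False))
    )
    if "gtf" in cl:
        index = annotation.build_annotation_index(cl["gtf"])
        out = clip.annotate_peaks(index, out)
    emit(out, "peak_enrichment.tsv")


def _run_score(config: PipelineConfig, emit) -> None:
    from .simulate import read_cell_matrix_tsv

    sc = config.score
    adata = read_cell_matrix_tsv(sc["matrix"], mito_prefix=sc.get("mito_prefix", "MT-"))
    filtered, report = expression.qc_filter(
        adata,
        min_cells_per_gene=int(sc.get("min_cells_per_gene", 5)),
        min_genes_per_cell=int(sc.get("min_genes_per_cell", 200)),
        max_mito_frac=float(sc.get("max_mito_frac", 0.10)),
    )
    emit(pd.DataFrame([report]), "qc_report.tsv")
    signature = sc.get("signature", [])
    if signature:
        scores = expression.score_signature(filtered, list(signature))
        emit(scores.rename_axis("cell").reset_index(), "signature_scores.tsv")
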