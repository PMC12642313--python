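"""Synthetic-data generators with known ground truth.

Every input the pipeline consumes can be generated here under a seed:

* :func:`simulate_junctions` — STAR-style junction count tables in which each
  donor site carries a canonical junction and a cryptic junction whose usage
  follows ``cryptic ~ Binomial(coverage, ψ_true)`` (so Ψ is a binomial
  proportion); planted sites switch ψ between conditions, null sites keep the
  control ψ in both.
* :func:`build_toy_genome` — a ≥3-exon protein-coding gene whose third intron
  hides a cryptic-exon cassette that, spliced in, keeps the upstream reading
  frame and encodes a chosen peptide followed by an in-frame stop (a
  PRDM2-like cassette when planted with the 14-residue peptide).
* :func:`simulate_peaks` — CLIP peak IP/input counts, Poisson around
  library-size-proportional rates, enriched peaks scaled by a true fold.
* :func:`simulate_cells` — negative-binomial gene-by-cell counts with a
  signature-enriched subpopulation.

All generators are bit-reproducible given their seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Mapping, Sequence

import anndata as ad
import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .consequence import TranscriptModel
from .junctions import write_junction_table

# Fixed most-common-codon table (human bias) for deterministic
# reverse-translation of planted peptides.
PREFERRED_CODON = {
    "A": "GCC", "C": "TGC", "D": "GAC", "E": "GAG", "F": "TTC", "G": "GGC",
    "H": "CAC", "I": "ATC", "K": "AAG", "L": "CTG", "M": "ATG", "N": "AAC",
    "P": "CCC", "Q": "CAG", "R": "AGA", "S": "AGC", "T": "ACC", "V": "GTG",
    "W": "TGG", "Y": "TAC",
}
STOP_CODON = "TAA"

# cyclic non-stop codon supply for filler coding sequence
_CODING_CYCLE = ["GCT", "GAA", "AAA", "CTG", "GAT", "TTT", "GGC", "CAC",
                 "ATT", "CCG", "AGC", "TGG", "TAT", "GTC", "CAG", "AAC"]


def _filler(n: int) -> str:
    return "".join(itertools.islice(itertools.cycle("TCAC"), n))


def _intron(n: int) -> str:
    if n < 4:
        raise ValueError("introns need at least 4 nt for GT..AG")
    return "GT" + _filler(n - 4) + "AG"


def _coding(n_codons: int, offset: int = 0) -> str:
    return "".join(
        _CODING_CYCLE[(offset + i) % len(_CODING_CYCLE)] for i in range(n_codons)
    )


def reverse_translate(peptide: str) -> str:
    """Deterministic reverse translation with the fixed preferred-codon table."""
    bad = set(peptide) - set(PREFERRED_CODON)
    if bad:
        raise ValueError(f"non-standard residues in peptide: {sorted(bad)}")
    return "".join(PREFERRED_CODON[aa] for aa in peptide)


# ---------------------------------------------------------------------------
# Junction simulation
# ---------------------------------------------------------------------------

@dataclass
class SpliceSimSpec:
    """Conditions for the junction-usage simulation.

    Each of ``n_sites`` donor sites has a canonical junction and a cryptic
    junction sharing the donor.  Per replicate, ``coverage`` junction-spanning
    reads split as cryptic ~ Binomial(coverage, ψ) with canonical taking the
    rest.  Sites in ``planted_sites`` use ``psi_case`` in the case condition;
    all other site/condition combinations use ``psi_control``.
    """

    n_sites: int = 200
    replicates_per_condition: int = 3
    coverage: int = 100
    psi_control: float = 0.01
    psi_case: float = 0.20
    planted_sites: tuple[int, ...] = tuple(range(20))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.coverage <= 0:
            raise ValueError(f"coverage must be positive, got {self.coverage}")
        for name in ("psi_control", "psi_case"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        self.planted_sites = tuple(self.planted_sites)
        if any(s < 0 or s >= self.n_sites for s in self.planted_sites):
            raise ValueError("planted_sites must be within range(n_sites)")
        if self.n_sites <= 0 or self.replicates_per_condition <= 0:
            raise ValueError("n_sites and replicates_per_condition must be positive")


# fixed geometry of a simulated site (0-based half-open, plus strand)
_SITE_SPAN = 10_000
_EXON_LEN = 200
_CANONICAL_INTRON = 5_000
_CRYPTIC_OFFSET = 2_000


def _site_coords(site: int) -> dict:
    offset = 1_000 + site * _SITE_SPAN
    donor = offset + _EXON_LEN
    return {
        "exon1": (offset, donor),
        "donor": donor,
        "canonical": (donor, donor + _CANONICAL_INTRON),
        "cryptic": (donor, donor + _CRYPTIC_OFFSET),
        "exon2": (donor + _CANONICAL_INTRON, donor + _CANONICAL_INTRON + _EXON_LEN),
    }


@dataclass
class JunctionSimulation:
    tables: dict[str, pd.DataFrame]  # sample -> long junction table
    truth: pd.DataFrame
    conditions: dict[str, str]  # sample -> condition
    chrom: str
    spec: SpliceSimSpec

    def counts_long(self) -> pd.DataFrame:
        return pd.concat(self.tables.values(), ignore_index=True)

    def write_star_tables(self, outdir: str | Path) -> list[Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = []
        for sample, df in self.tables.items():
            p = outdir / f"{sample}.SJ.out.tab"
            write_junction_table(df, p, dialect="star_sj")
            paths.append(p)
        return paths

    def write_truth(self, path: str | Path) -> None:
        self.truth.to_csv(path, sep="\t", index=False)

    def write_gtf(self, path: str | Path) -> None:
        """Annotation containing only the canonical two-exon transcripts."""
        with open(path, "w") as fh:
            for site in range(self.spec.n_sites):
                c = _site_coords(site)
                gene = f"SIMG{site:04d}"
                tx = f"{gene}.1"
                attrs = (
                    f'gene_id "{gene}"; transcript_id "{tx}"; '
                    f'gene_biotype "protein_coding";'
                )
                for s, e in (c["exon1"], c["exon2"]):
                    fh.write(
                        f"{self.chrom}\tsim\texon\t{s + 1}\t{e}\t.\t+\t.\t{attrs}\n"
                    )


def simulate_junctions(spec: SpliceSimSpec) -> JunctionSimulation:
    """Draw junction count tables plus a truth table of planted events."""
    rng = np.random.default_rng(spec.seed)
    chrom = "chrSJ"
    planted = set(spec.planted_sites)
    samples = {
        f"{cond}_rep{r + 1}": cond
        for cond in ("control", "case")
        for r in range(spec.replicates_per_condition)
    }
    tables: dict[str, pd.DataFrame] = {}
    for sample, cond in samples.items():
        rows = []
        for site in range(spec.n_sites):
            c = _site_coords(site)
            psi = (
                spec.psi_case
                if (site in planted and cond == "case")
                else spec.psi_control
            )
            cryptic = int(rng.binomial(spec.coverage, psi))
            canonical = spec.coverage - cryptic
            rows.append((chrom, *c["canonical"], "+", canonical))
            if cryptic > 0:
                rows.append((chrom, *c["cryptic"], "+", cryptic))
        df = pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "reads"])
        df["sample"] = sample
        tables[sample] = df

    truth = pd.DataFrame(
        [
            {
                "site": site,
                "chrom": chrom,
                "cryptic_start": _site_coords(site)["cryptic"][0],
                "cryptic_end": _site_coords(site)["cryptic"][1],
                "strand": "+",
                "planted": site in planted,
                "psi_control": spec.psi_control,
                "psi_case": spec.psi_case if site in planted else spec.psi_control,
            }
            for site in range(spec.n_sites)
        ]
    )
    return JunctionSimulation(tables=tables, truth=truth, conditions=samples, chrom=chrom, spec=spec)


# ---------------------------------------------------------------------------
# Toy genome with a planted cryptic exon
# ---------------------------------------------------------------------------

@dataclass
class ToyGenome:
    """A one-gene toy genome whose intron 3 hides a cryptic-exon cassette."""

    chrom: str
    sequence: str
    model: TranscriptModel
    ce_interval: tuple[int, int]  # genomic, 0-based half-open
    ce_sequence: str  # sense-strand cassette sequence
    peptide: str  # planted cryptic peptide
    expected_truncated_length: int  # residues of the CE-truncated product
    reference_protein: str
    cryptic_junctions: list[tuple[int, int]] = dc_field(default_factory=list)

    @property
    def genome(self) -> dict[str, str]:
        return {self.chrom: self.sequence}

    def write_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f">{self.chrom}\n")
            for i in range(0, len(self.sequence), 70):
                fh.write(self.sequence[i : i + 70] + "\n")

    def write_gtf(self, path: str | Path) -> None:
        m = self.model
        attrs = (
            f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}"; '
            f'gene_biotype "protein_coding";'
        )
        lines = []
        gstart, gend = m.exons[0][0], m.exons[-1][1]
        lines.append((gstart, gend, "gene"))
        lines.append((gstart, gend, "transcript"))
        for s, e in m.exons:
            lines.append((s, e, "exon"))
        for s, e in self._cds_genomic():
            lines.append((s, e, "CDS"))
        with open(path, "w") as fh:
            for s, e, feat in lines:
                fh.write(f"{self.chrom}\ttoy\t{feat}\t{s + 1}\t{e}\t.\t{m.strand}\t.\t{attrs}\n")

    def _cds_genomic(self) -> list[tuple[int, int]]:
        """Genomic CDS pieces (stop codon included) from transcript CDS coords."""
        m = self.model
        pieces = []
        # transcript coordinate walk over exons in 5'→3' order
        exons = m.exons if m.strand != "-" else m.exons[::-1]
        off = 0
        for s, e in exons:
            ln = e - s
            lo = max(m.cds_start, off)
            hi = min(m.cds_end, off + ln)
            if lo < hi:
                if m.strand == "-":
                    pieces.append((e - (hi - off), e - (lo - off)))
                else:
                    pieces.append((s + (lo - off), s + (hi - off)))
            off += ln
        return sorted(pieces)


def build_toy_genome(
    peptide: str = "VPDTLWTLSRYLNE",
    ce_length: int = 490,
    strand: str = "+",
    include_stop: bool = True,
    upstream_residues: int = 42,
) -> ToyGenome:
    """Construct the toy genome around a planted cryptic-exon cassette.

    The gene has four exons; the intron between exons 3 and 4 contains the
    cassette.  Cumulative coding sequence upstream of that intron is
    ``3 * upstream_residues`` nt, so the cassette is read in frame: its first
    codons encode ``peptide``, followed by an in-frame stop (default) and
    deterministic padding to ``ce_length``.  With ``include_stop=False`` the
    cassette is stop-free and ``ce_length`` must be a multiple of 3 (a
    frame-preserving insertion).  The expected truncated product is
    ``upstream_residues + len(peptide)`` residues.

    ``strand='-'`` mirrors the whole construction onto the minus strand.
    """
    if strand not in "+-":
        raise ValueError("strand must be '+' or '-'")
    core = reverse_translate(peptide) + (STOP_CODON if include_stop else "")
    if ce_length < len(core):
        raise ValueError(
            f"ce_length={ce_length} too small: peptide plus stop needs {len(core)} nt"
        )
    if not include_stop:
        if ce_length % 3:
            raise ValueError("stop-free cassettes must have length divisible by 3")
        pad_codons = (ce_length - len(core)) // 3
        ce_seq = core + _coding(pad_codons, offset=7)
    else:
        ce_seq = core + _filler(ce_length - len(core))
    assert len(ce_seq) == ce_length

    if upstream_residues < 26:
        raise ValueError("upstream_residues must be >= 26 for the fixed exon layout")
    utr5, utr3 = 20, 20
    exon1_cds, exon2_cds = 30, 45
    exon3_cds = 3 * upstream_residues - exon1_cds - exon2_cds
    exon4_cds = 90  # 30 codons before the reference stop

    n_up = upstream_residues - 1  # codons after ATG, upstream of the cassette intron
    cds_seq = "ATG" + _coding(n_up) + _coding(30, offset=n_up) + STOP_CODON
    reference_protein = str(Seq(cds_seq).translate())[:-1]  # drop '*'

    exon1 = _filler(utr5) + cds_seq[:exon1_cds]
    exon2 = cds_seq[exon1_cds : exon1_cds + exon2_cds]
    exon3 = cds_seq[exon1_cds + exon2_cds : exon1_cds + exon2_cds + exon3_cds]
    exon4 = cds_seq[exon1_cds + exon2_cds + exon3_cds :] + _filler(utr3)

    up_intron, down_intron = _intron(200), _intron(150)
    pad = _filler(100)
    parts = [
        pad, exon1, _intron(80), exon2, _intron(80), exon3,
        up_intron, ce_seq, down_intron, exon4, pad,
    ]
    seq = "".join(parts)

    # genomic coordinates (plus-strand layout)
    pos = 0
    coords = {}
    for name, part in zip(
        ["pad0", "exon1", "i1", "exon2", "i2", "exon3", "up_intron", "ce", "down_intron", "exon4", "pad1"],
        parts,
    ):
        coords[name] = (pos, pos + len(part))
        pos += len(part)

    exons = [coords["exon1"], coords["exon2"], coords["exon3"], coords["exon4"]]
    ce_interval = coords["ce"]
    cds_start_tx = utr5
    cds_end_tx = utr5 + len(cds_seq)
    cryptic_junctions = [
        (coords["exon3"][1], ce_interval[0]),  # annotated donor -> cassette acceptor
        (ce_interval[1], coords["exon4"][0]),  # cassette donor -> annotated acceptor
    ]

    if strand == "-":
        total = len(seq)
        seq = str(Seq(seq).reverse_complement())
        mirror = lambda iv: (total - iv[1], total - iv[0])  # noqa: E731
        exons = sorted(mirror(iv) for iv in exons)
        ce_interval = mirror(ce_interval)
        ce_seq_store = ce_seq  # sense-strand cassette sequence is unchanged
        cryptic_junctions = sorted(mirror(iv) for iv in cryptic_junctions)
    else:
        ce_seq_store = ce_seq

    model = TranscriptModel(
        gene_id="TOYG1",
        transcript_id="TOYG1.1",
        chrom="chrT",
        strand=strand,
        exons=exons,
        cds_start=cds_start_tx,
        cds_end=cds_end_tx,
    )
    return ToyGenome(
        chrom="chrT",
        sequence=seq,
        model=model,
        ce_interval=ce_interval,
        ce_sequence=ce_seq_store,
        peptide=peptide,
        expected_truncated_length=upstream_residues + len(peptide),
        reference_protein=reference_protein,
        cryptic_junctions=cryptic_junctions,
    )


# ---------------------------------------------------------------------------
# CLIP peak simulation
# ---------------------------------------------------------------------------

@dataclass
class ClipSimSpec:
    """Conditions for the peak-count simulation.

    Null peaks draw IP and input reads from Poisson with rates proportional
    to the library sizes (``background_rate`` expected input reads per peak);
    peaks in ``enriched_peaks`` (id → true fold) scale the IP rate.  Setting
    ``dispersion`` switches to a gamma-Poisson (negative-binomial) draw.
    """

    n_peaks: int = 2_000
    library_size_ip: int = 1_000_000
    library_size_input: int = 1_000_000
    enriched_peaks: Mapping[int, float] = dc_field(default_factory=dict)
    background_rate: float = 100.0
    dispersion: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.library_size_ip <= 0 or self.library_size_input <= 0:
            raise ValueError("library sizes must be positive")
        if self.background_rate <= 0:
            raise ValueError("background_rate must be positive")
        bad = [i for i in self.enriched_peaks if not 0 <= i < self.n_peaks]
        if bad:
            raise ValueError(f"enriched peak ids outside range(n_peaks): {bad}")


@dataclass
class PeakSimulation:
    peaks: pd.DataFrame  # peak_id, chrom, start, end, strand, reads_ip, reads_input
    truth: pd.DataFrame
    total_ip: int
    total_input: int

    def write_bed(self, path: str | Path) -> None:
        bed = self.peaks[["chrom", "start", "end", "peak_id", "strand"]].copy()
        bed.insert(4, "score", 0)
        bed.to_csv(path, sep="\t", header=False, index=False)

    def write_counts(self, path: str | Path) -> None:
        df = self.peaks.copy()
        df["total_ip"] = self.total_ip
        df["total_input"] = self.total_input
        df.to_csv(path, sep="\t", index=False)

    def write_truth(self, path: str | Path) -> None:
        self.truth.to_csv(path, sep="\t", index=False)


def simulate_peaks(spec: ClipSimSpec) -> PeakSimulation:
    """Draw IP/input read counts per peak with known enrichment truth."""
    rng = np.random.default_rng(spec.seed)
    fold = np.ones(spec.n_peaks)
    for pid, f in spec.enriched_peaks.items():
        fold[pid] = f
    lam_input = np.full(spec.n_peaks, spec.background_rate)
    lam_ip = lam_input * (spec.library_size_ip / spec.library_size_input) * fold
    if spec.dispersion is not None:
        if spec.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        shape = 1.0 / spec.dispersion
        lam_ip = rng.gamma(shape, lam_ip / shape)
        lam_input = rng.gamma(shape, lam_input / shape)
    reads_ip = rng.poisson(lam_ip)
    reads_input = rng.poisson(lam_input)

    peaks = pd.DataFrame(
        {
            "peak_id": [f"peak_{i:05d}" for i in range(spec.n_peaks)],
            "chrom": "chrP",
            "start": np.arange(spec.n_peaks) * 1_000,
            "end": np.arange(spec.n_peaks) * 1_000 + 100,
            "strand": "+",
            "reads_ip": reads_ip,
            "reads_input": reads_input,
        }
    )
    truth = pd.DataFrame(
        {
            "peak_id": peaks["peak_id"],
            "enriched": fold > 1.0,
            "true_fold": fold,
        }
    )
    return PeakSimulation(
        peaks=peaks, truth=truth,
        total_ip=spec.library_size_ip, total_input=spec.library_size_input,
    )


# ---------------------------------------------------------------------------
# Single-cell count simulation
# ---------------------------------------------------------------------------

@dataclass
class CellSimSpec:
    """Conditions for the single-cell count simulation.

    Counts are negative-binomial around lognormally distributed per-gene base
    means (var = μ + dispersion·μ²).  Signature genes are up-shifted by
    ``signature_log2fc`` in signature cells — a stand-in for a small
    signature-enriched subpopulation (≈5% of cells by default, mirroring an
    immature-neuron population).  ``mito_genes`` are flagged for QC.
    """

    n_cells: int = 2_000
    n_genes: int = 1_000
    signature_genes: Sequence[str] = tuple(f"SIG{i:03d}" for i in range(50))
    signature_cells: Sequence[str] | None = None  # default: first 5% of cells
    signature_log2fc: float = 2.0
    dispersion: float = 0.5
    mito_genes: Sequence[str] = tuple(f"MT-G{i}" for i in range(10))
    base_mean: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells <= 0 or self.n_genes <= 0:
            raise ValueError("empty gene/cell universe")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        n_named = len(self.signature_genes) + len(self.mito_genes)
        if n_named > self.n_genes:
            raise ValueError("signature + mito genes exceed the gene universe")


def simulate_cells(spec: CellSimSpec) -> ad.AnnData:
    """Draw a cells × genes count matrix with planted-signature truth labels.

    Returns an AnnData with ``obs['planted']`` (signature cell flag) and
    ``var['mito']`` / ``var['signature']``.
    """
    rng = np.random.default_rng(spec.seed)
    sig_genes = list(spec.signature_genes)
    mito = list(spec.mito_genes)
    n_other = spec.n_genes - len(sig_genes) - len(mito)
    genes = sig_genes + mito + [f"G{i:05d}" for i in range(n_other)]
    cells = [f"cell_{i:05d}" for i in range(spec.n_cells)]
    if spec.signature_cells is None:
        sig_cells = set(cells[: max(1, spec.n_cells // 20)])
    else:
        sig_cells = set(spec.signature_cells)
        if not sig_cells <= set(cells):
            raise ValueError("signature_cells outside the cell universe")
    planted = np.array([c in sig_cells for c in cells])

    base = rng.lognormal(mean=np.log(spec.base_mean), sigma=1.0, size=spec.n_genes)
    # mitochondrial genes run hotter than average; the factor keeps the
    # expected mito fraction in the healthy 2-5% range, clear of the QC cutoff
    base[len(sig_genes) : len(sig_genes) + len(mito)] *= 3
    mu = np.tile(base, (spec.n_cells, 1))
    mu[np.ix_(planted, np.arange(len(sig_genes)))] *= 2.0 ** spec.signature_log2fc

    r = 1.0 / spec.dispersion  # NB size parameter
    p = r / (r + mu)
    counts = rng.negative_binomial(r, p)

    adata = ad.AnnData(
        X=counts.astype(np.float32),
        obs=pd.DataFrame({"planted": planted}, index=cells),
        var=pd.DataFrame(
            {
                "mito": [g in set(mito) for g in genes],
                "signature": [g in set(sig_genes) for g in genes],
            },
            index=genes,
        ),
    )
    adata.uns["spec_seed"] = spec.seed
    return adata


def write_cell_matrix_tsv(adata: ad.AnnData, path: str | Path) -> None:
    """Genes × cells counts as TSV (genes as rows)."""
    df = pd.DataFrame(
        np.asarray(adata.X).T, index=adata.var_names, columns=adata.obs_names
    )
    df.to_csv(path, sep="\t")


def read_cell_matrix_tsv(path: str | Path, mito_prefix: str = "MT-") -> ad.AnnData:
    df = pd.read_csv(path, sep="\t", index_col=0)
    adata = ad.AnnData(
        X=df.to_numpy().T.astype(np.float32),
        obs=pd.DataFrame(index=df.columns),
        var=pd.DataFrame({"mito": df.index.str.startswith(mito_prefix)}, index=df.index),
    )
    return adata


# ---------------------------------------------------------------------------
# Fixture materialisation
# ---------------------------------------------------------------------------

def materialize_fixtures(outdir: str | Path, seed: int = 0) -> dict[str, Path]:
    """Write a complete demo dataset (junctions, toy genome, peaks, cells)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    jsim = simulate_junctions(SpliceSimSpec(seed=seed))
    jdir = outdir / "junctions"
    jsim.write_star_tables(jdir)
    jsim.write_gtf(jdir / "annotation.gtf")
    jsim.write_truth(jdir / "truth.tsv")
    paths["junctions"] = jdir

    toy = build_toy_genome()
    toy.write_fasta(outdir / "toy_genome.fa")
    toy.write_gtf(outdir / "toy_genome.gtf")
    paths["toy_fasta"] = outdir / "toy_genome.fa"
    paths["toy_gtf"] = outdir / "toy_genome.gtf"

    n_enriched = 100
    psim = simulate_peaks(
        ClipSimSpec(enriched_peaks={i: 4.0 for i in range(n_enriched)}, seed=seed + 1)
    )
    psim.write_bed(outdir / "peaks.bed")
    psim.write_counts(outdir / "peak_counts.tsv")
    psim.write_truth(outdir / "peak_truth.tsv")
    paths["peaks"] = outdir / "peak_counts.tsv"

    adata = simulate_cells(CellSimSpec(seed=seed + 2))
    write_cell_matrix_tsv(adata, outdir / "cells.tsv")
    adata.obs.to_csv(outdir / "cell_truth.tsv", sep="\t")
    paths["cells"] = outdir / "cells.tsv"
    return paths
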