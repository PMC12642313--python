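# Methods

## Junction-level Ψ

A splice junction is an intron interval (0-based half-open internally; the
STAR `SJ.out.tab` dialect with 1-based inclusive intron coordinates is
converted at the I/O boundary).  For junction *j* in one sample,

Ψ_j = r_j / Σ_{k ∈ C(j)} r_k,

where r is the uniquely-mapping junction-spanning read count (multi-mapped
reads are excluded because they inflate junction counts) and C(j) is the
*competing set*.  The default competing set is the union of junctions sharing
*j*'s donor **or** acceptor site on the same chromosome and strand, which
detects cryptic donors and cryptic acceptors symmetrically; `mode="donor"` /
`"acceptor"` restrict the denominator to one side.  A zero denominator
leaves Ψ undefined (NaN), which is deliberately distinct from Ψ = 0: a
junction observed in one sample but silent in another scores Ψ = 0 there
only if its competitors were observed.  Condition means are taken over
replicates where Ψ is defined, and ΔΨ = Ψ̄_case − Ψ̄_control.

Within a competing set that is *closed* (every member shares a site with
every other, as when one donor feeds several acceptors), Σ Ψ = 1 exactly in
every sample with a non-zero denominator.  With chained sharing (A–B share a
donor, B–C an acceptor) the union denominator of B is larger than either
group and the per-site sums deviate from 1; the simulated data, like most
cryptic-splicing geometries, consist of disjoint donor-sharing cliques where
the identity holds and is asserted by the tests.

## Cryptic-event calling

A junction is called cryptic iff (strict inequalities, matching the printed
thresholds): Ψ̄_control < 0.05, ΔΨ > 0.10, and the junction is absent from
the annotation index (exact coordinate and strand equality; one-off
coordinates are distinct splice sites).  ΔΨ is signed — only inclusion
*gains* in the case condition are cryptic, mirroring cryptic-exon
de-repression in the mutant; `signed=False` switches to |ΔΨ| for callers who
want both directions.  The annotated-junction set is derived from a GTF as
the interval between consecutive exons of each transcript (gffutils
in-memory database; duplicates collapsed; exons sorted per transcript).
Event classes follow which end is annotated: donor only → cryptic acceptor,
acceptor only → cryptic donor, neither → other-unannotated.  Junctions of
unknown strand are matched against both strands and flagged.

Two cryptic junctions inside one annotated intron of one gene are paired
into a cryptic exon when the genomic-left junction starts at the intron's
left boundary and ends inside it and the genomic-right junction mirrors this
(donor/acceptor roles swap with strand; the geometry does not).  The CE
interval is the gap between the interior junction ends; zero-width cassettes
are rejected as degenerate.

## Protein consequence of a CE inclusion

The CE-containing mature mRNA is the exon concatenation with the cassette
inserted between its flanking exons (reverse-complemented for minus-strand
genes).  Translation runs from the annotated start codon to the first stop
under the standard genetic code.  A residue belongs to the cryptic peptide
iff its codon's **first base** lies inside the CE's transcript-coordinate
span — an unambiguous convention for codons spanning the CE boundary.  The
same convention decides `stop_in_ce`.  Products without an in-frame stop are
flagged non-stop rather than silently truncated.

NMD candidacy uses the 50-nt heuristic: the transcript is a candidate iff
more than `rule_nt` (default 50, configurable to the 55-nt variant)
nucleotides separate the last base of the stop codon from the final
exon-exon junction.  A stop in the final exon is never a candidate.

## The toy genome

`build_toy_genome` constructs a four-exon protein-coding gene whose third
intron carries the cassette.  The layout fixes the cumulative coding length
upstream of that intron to 3 × 42 nt, so the cassette is read in frame: its
first codons are the deterministic reverse-translation of the requested
peptide (fixed most-common-codon table, for bit-reproducibility), followed
by an in-frame TAA and neutral padding to the requested length.  With the
default 14-residue peptide the truncated product is 42 + 14 = 56 residues
against a 72-residue reference — the arithmetic of a PRDM2-like cassette.
All annotated and cryptic intron boundaries carry GT..AG dinucleotides.  A
stop-free variant (`include_stop=False`, length ≡ 0 mod 3) produces a pure
in-frame insertion for testing the non-truncating path.  The minus-strand
variant is the exact mirror image of the plus-strand construction, giving an
independent strand oracle: both must yield the same mature mRNA.

## Simulators and what they emulate

- **Junctions**: each donor site has a canonical junction and one cryptic
  junction sharing the donor; per replicate, cryptic reads ~
  Binomial(coverage, ψ) with the canonical junction taking the remainder, so
  Ψ is exactly a binomial proportion.  Defaults are the study conditions
  used throughout: 200 sites, 20 planted, coverage 100, ψ_control = 0.01,
  ψ_case = 0.20, three replicates per condition.  Not emulated: overhang
  filters, multi-mapping, coverage variation along the gene — so passing
  tests demonstrate the statistical layer, not aligner behaviour.
- **Peaks**: IP and input counts are Poisson around rates proportional to
  the library sizes; enriched peaks scale the IP rate by their true fold.
  The default background of 100 expected reads per peak reflects typical
  CLIP peak depth and keeps the large-sample χ² regime meaningful (at this
  depth the Yates correction shifts the null rejection rate to ≈0.04–0.05).
  An optional dispersion parameter switches to gamma-Poisson draws.
- **Cells**: negative-binomial counts (var = μ + αμ², α = 0.5) around
  lognormal per-gene means (median ≈ 0.5 counts/cell); a 5% subpopulation —
  the size of the immature-neuron population the signature score was built
  for — has its 50 signature genes shifted by 2^log2fc.  Mitochondrial
  genes run ~3× hot, placing typical cells in the healthy 2–5% mito range,
  clear of the 10% QC cutoff.  Library-size variation and dropout beyond NB
  sampling are not modelled.

## Enrichment statistics

Fold enrichment is (k₁/n₁)/(k₂/n₂); it is exactly invariant to rescaling
one library's (k, n) by a common factor.  k₂ = 0 with k₁ > 0 is reported as
an infinite ratio (no pseudocount by default); k₁ = k₂ = 0 as undefined.
The p-value comes from Yates'-corrected χ² on [[k₁, n₁−k₁], [k₂, n₂−k₂]]
(scipy), switching to the two-sided Fisher exact test whenever any observed
cell **or** any expected cell of that table is below 5 — "observed or
expected" is read as any of the four cells, the conservative reading.
Tests are two-sided; direction is the side of 1 the fold falls on.
Benjamini–Hochberg FDR is available as an opt-in column and off by default
(the workflow this mirrors reports raw p-values).  P-values are clamped to
(0, 1].

The Fisher branch is validated against an exhaustive hypergeometric
enumeration (sum of all table probabilities ≤ the observed table's, with
the standard (1+1e-7) floating-point tie guard) over every 2×2 table with
both row margins ≤ 30.  Agreement between the χ² and Fisher branches within
a factor of two is asserted in the regime the switchover rule is about —
tables from the null count model with all cells ≥ 20; for arbitrary extreme
tables both p-values become astronomically small and relative agreement is
not meaningful.

## Expression thresholds

All boundary conventions follow the printed criteria exactly and are pinned
by boundary tests: genes kept when expressed in **more than** 5 cells; cells
dropped when detected genes < 200 or mitochondrial fraction **≥** 10% (a
cell at exactly 10% is removed); bulk DEGs at padj < 0.05 and |log2FC| > 1
(strict); cluster markers at padj < 0.05, pct ≥ 10%, log2FC ≥ 1 (inclusive,
up only); signature genes at pct ≥ 20%, padj < 0.05 and **linear** fold
change ≥ 4 (a `fc_scale` flag covers the log2 reading).  The gene filter
runs before the cell filter, so detected-gene counts refer to retained
genes.  The filter is idempotent on realistic matrices; in principle
removing cells can drop a borderline gene below the 5-cell floor on a second
pass, which the QC report would surface.

Signature scores are the per-cell arithmetic mean over signature genes,
computed by default on library-size-normalised (10,000 counts) log1p
expression, matching scoring on processed single-cell data; a raw-count
mode exists.  The score is linear: the score of a disjoint union of
signatures is the size-weighted mean of the parts.

The rescue rule compares |log2FC| between the untreated and treated
contrasts (strict <) and requires the untreated-contrast p < 0.05; absolute
values are used so that both up- and down-dysregulated genes can be
rescued, with a signed mode for the directional reading.

## Problem sizes

The shipped analyses and tests run at the study conditions above (hundreds
of junctions and peaks, 2,000 cells × 1,000 genes), sizes at which every
statistical check (3-SE recovery bands, Monte-Carlo calibration within 3 SE
of the nominal 0.05, ≥95% recall / ≤1% false positives) is well-powered
while the full suite completes in a few minutes.

## Known limitations

- Junction annotation matching is exact-coordinate; fuzzy matching for
  mis-annotated boundaries is out of scope.
- The union competing set can exceed a single site's junction group under
  chained sharing (see above); per-site Σ Ψ = 1 is guaranteed only for
  closed sets.
- The consequence predictor evaluates one transcript model per gene at a
  time; isoform-aware aggregation is the caller's responsibility.
- Selenocysteine, stop-codon readthrough and non-standard genetic codes are
  not supported.
- NMD candidacy is a heuristic rule, not a decay-efficiency prediction.
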