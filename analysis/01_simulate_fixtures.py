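#!/usr/bin/env python
"""Generate every synthetic input the downstream analyses consume.

Writes, under results/fixtures/: STAR-style junction tables (3 control + 3
case replicates, 200 donor sites, 20 planted cryptic junctions), the matching
canonical-transcript GTF and truth table; the toy genome (FASTA + GTF) whose
third intron hides a 490-nt cryptic-exon cassette encoding the 14-residue
peptide VPDTLWTLSRYLNE; CLIP peak counts (2,000 peaks, 100 enriched 4-fold);
and a negative-binomial single-cell matrix with a planted 5% signature-high
subpopulation.
"""

from pathlib import Path

from crypticflow.simulate import materialize_fixtures

OUT = Path(__file__).resolve().parent.parent / "results" / "fixtures"

if __name__ == "__main__":
    paths = materialize_fixtures(OUT, seed=0)
    print("fixture set written with seed 0:")
    for name, p in paths.items():
        print(f"  {name:12s} {p}")
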