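#!/usr/bin/env python
"""CLIP peak enrichment statistics and binding-set overlap.

Runs the χ²/Fisher switchover enrichment test over the simulated peak counts
from 01, reports detection of the planted 4-fold peaks and the null
false-positive rate, and reproduces the binding-set algebra for the published
bound-gene counts (5,143 WT vs 4,354 mutant genes, 1,260/471 exclusive).
Writes peak_enrichment.tsv and binding_overlap.tsv under results/clip/.
"""

from pathlib import Path

import pandas as pd

from crypticflow import clip

ROOT = Path(__file__).resolve().parent.parent / "results"
FIX = ROOT / "fixtures"
OUT = ROOT / "clip"

if __name__ == "__main__":
    OUT.mkdir(parents=True, exist_ok=True)
    counts = pd.read_csv(FIX / "peak_counts.tsv", sep="\t")
    res = clip.enrichment_table(
        counts, "reads_ip", int(counts.total_ip.iloc[0]),
        "reads_input", int(counts.total_input.iloc[0]),
    )
    res.to_csv(OUT / "peak_enrichment.tsv", sep="\t", index=False)

    truth = pd.read_csv(FIX / "peak_truth.tsv", sep="\t")
    merged = res.merge(truth, on="peak_id")
    hit = (merged.p_value < 0.05) & (merged.direction == "up")
    power = hit[merged.enriched].mean()
    fpr = (merged.p_value < 0.05)[~merged.enriched].mean()
    print(f"planted 4-fold peaks detected: {power:.1%}; null rejection at 0.05: {fpr:.3f}")
    print(f"tests used: {res.test_used.value_counts().to_dict()}")

    ov = clip.BindingOverlap.from_counts(5143, 4354, a_only=1260, b_only=471)
    row = {
        "size_wt": ov.size_a, "size_mut": ov.size_b, "wt_only": ov.a_only,
        "mut_only": ov.b_only, "shared": ov.shared, "union": ov.union,
        "pct_shared": round(ov.fraction_of_union("shared"), 1),
        "pct_wt_only": round(ov.fraction_of_union("a_only"), 1),
        "pct_mut_only": round(ov.fraction_of_union("b_only"), 1),
    }
    pd.DataFrame([row]).to_csv(OUT / "binding_overlap.tsv", sep="\t", index=False)
    print(f"binding overlap: {ov.shared} shared genes = {row['pct_shared']}% of the "
          f"{ov.union}-gene union; {row['pct_wt_only']}% bound WT only")
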