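#!/usr/bin/env python
"""Protein consequence of the planted cryptic exon in the toy genome.

Loads the toy genome (FASTA + GTF) from 01, pairs the cassette's two cryptic
junctions inside the annotated intron, splices the cassette into the
transcript, translates to the premature stop, and applies the 50-nt NMD rule.
Writes ce_consequences.tsv under results/consequence/ and prints the
truncated-product arithmetic (42 reference residues + 14 cryptic = 56).
"""

from pathlib import Path

import pandas as pd

from crypticflow import consequence as cq
from crypticflow.simulate import build_toy_genome

ROOT = Path(__file__).resolve().parent.parent / "results"
OUT = ROOT / "consequence"

if __name__ == "__main__":
    OUT.mkdir(parents=True, exist_ok=True)
    toy = build_toy_genome(peptide="VPDTLWTLSRYLNE", ce_length=490)

    ref = cq.translate_with_ce(cq.mature_mrna(toy.model, toy.genome))
    spliced = cq.splice_in_ce(toy.model, toy.ce_interval, toy.genome)
    product = cq.translate_with_ce(spliced, reference_protein_length=len(ref.protein))
    cq.flag_nmd(product, spliced)

    row = {
        "gene": toy.model.gene_id,
        "transcript": toy.model.transcript_id,
        "ce_start": toy.ce_interval[0],
        "ce_end": toy.ce_interval[1],
        "ce_length": toy.ce_interval[1] - toy.ce_interval[0],
        "reference_length_aa": len(ref.protein),
        "product_length_aa": product.length,
        "cryptic_suffix": product.cryptic_suffix,
        "cryptic_suffix_length": len(product.cryptic_suffix),
        "stop_in_ce": product.stop_in_ce,
        "truncated": product.truncated,
        "nmd_candidate": product.nmd_candidate,
    }
    pd.DataFrame([row]).to_csv(OUT / "ce_consequences.tsv", sep="\t", index=False)
    print(
        f"cassette of {row['ce_length']} nt -> truncated product of "
        f"{row['product_length_aa']} aa with {row['cryptic_suffix_length']}-residue "
        f"cryptic C-terminal peptide {row['cryptic_suffix']} "
        f"(reference {row['reference_length_aa']} aa); NMD candidate: {row['nmd_candidate']}"
    )
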