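"""Peak enrichment statistics, annotation hierarchy and binding-set algebra."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats
from scipy.stats import hypergeom

from crypticflow import clip
from crypticflow.annotation import build_annotation_index
from crypticflow.simulate import ClipSimSpec, simulate_peaks


def fisher_oracle(k1: int, n1: int, k2: int, n2: int) -> float:
    """Exhaustive hypergeometric enumeration of the two-sided Fisher p."""
    N, K = n1 + n2, k1 + k2
    xs = np.arange(max(0, K - n2), min(K, n1) + 1)
    pmf = hypergeom.pmf(xs, N, K, n1)
    pk = hypergeom.pmf(k1, N, K, n1)
    return float(min(pmf[pmf <= pk * (1 + 1e-7)].sum(), 1.0))


class TestEnrichmentTest:
    def test_normalised_ratio(self):
        r = clip.enrichment_test(100, 10**6, 10, 2 * 10**6)
        assert r.fold_enrichment == pytest.approx(20.0)
        assert r.direction == "up"

    def test_symmetric_table_unit_fold(self):
        r = clip.enrichment_test(50, 10_000, 50, 10_000)
        assert r.fold_enrichment == 1.0
        assert r.direction == "unchanged"
        assert r.p_value == pytest.approx(1.0, abs=1e-6)

    def test_small_cell_routes_to_fisher(self):
        r = clip.enrichment_test(4, 100, 0, 100)
        assert r.test_used == "fisher"
        assert r.p_value == pytest.approx(fisher_oracle(4, 100, 0, 100), abs=1e-12)

    def test_large_cells_route_to_yates(self):
        r = clip.enrichment_test(100, 10_000, 60, 10_000)
        assert r.test_used == "yates_chi2"
        expected = stats.chi2_contingency(
            [[100, 9_900], [60, 9_940]], correction=True
        ).pvalue
        assert r.p_value == pytest.approx(float(expected))

    def test_zero_counts_flagged(self):
        both = clip.enrichment_test(0, 100, 0, 100)
        assert np.isnan(both.fold_enrichment) and both.p_value == 1.0
        only_fg = clip.enrichment_test(5, 100, 0, 100)
        assert np.isinf(only_fg.fold_enrichment)

    def test_nonpositive_totals_rejected(self):
        with pytest.raises(ValueError):
            clip.enrichment_test(1, 0, 1, 10)

    def test_normalisation_invariance_of_fold(self):
        a = clip.enrichment_test(40, 10**6, 20, 10**6)
        b = clip.enrichment_test(40, 10**6, 200, 10**7)  # comparison library x10
        assert a.fold_enrichment == pytest.approx(b.fold_enrichment)

    def test_fisher_vs_yates_factor_two_in_null_regime(self):
        # tables from the null count model with all cells >= 20: the regimes
        # where the switchover matters, the two tests agree within 2x
        rng = np.random.default_rng(0)
        for _ in range(100):
            lam = int(rng.integers(20, 200))
            k1, k2 = rng.poisson(lam, 2) + 20
            n1 = n2 = 50_000
            pf = clip.fisher_two_sided(k1, n1, k2, n2)
            pc = float(stats.chi2_contingency(
                [[k1, n1 - k1], [k2, n2 - k2]], correction=True
            ).pvalue)
            assert pf / pc < 2 and pc / pf < 2

    def test_fdr_column_optional(self):
        df = pd.DataFrame({"reads_ip": [50, 60, 200], "reads_input": [50, 55, 50]})
        plain = clip.enrichment_table(df, "reads_ip", 10_000, "reads_input", 10_000)
        assert "padj" not in plain
        with_fdr = clip.enrichment_table(
            df, "reads_ip", 10_000, "reads_input", 10_000, fdr=True
        )
        assert (with_fdr["padj"] >= with_fdr["p_value"] - 1e-15).all()


class TestNullCalibration:
    def test_type_i_error_near_nominal(self):
        sim = simulate_peaks(ClipSimSpec(n_peaks=2_000, seed=21))
        res = clip.enrichment_table(
            sim.peaks, "reads_ip", sim.total_ip, "reads_input", sim.total_input
        )
        frac = (res.p_value < 0.05).mean()
        se = np.sqrt(0.05 * 0.95 / 2_000)
        assert abs(frac - 0.05) < 3 * se

    def test_planted_enrichment_detected(self):
        spec = ClipSimSpec(
            n_peaks=500, enriched_peaks={i: 4.0 for i in range(50)}, seed=22
        )
        sim = simulate_peaks(spec)
        res = clip.enrichment_table(
            sim.peaks, "reads_ip", sim.total_ip, "reads_input", sim.total_input
        )
        hit = res.merge(sim.truth, on="peak_id")
        assert ((hit.p_value < 0.05) & (hit.direction == "up"))[hit.enriched].mean() > 0.95


class TestCountReadsInPeaks:
    def _peaks(self):
        return pd.DataFrame(
            {"peak_id": ["p1"], "chrom": ["c"], "start": [100], "end": [200], "strand": ["+"]}
        )

    def test_overlap_rules(self):
        reads = pd.DataFrame(
            {
                "chrom": ["c"] * 4,
                "start": [120, 199, 200, 150],
                "end": [180, 260, 300, 160],
                "strand": ["+", "+", "+", "-"],
            }
        )
        out = clip.count_reads_in_peaks(self._peaks(), reads)
        # inside + 1-bp edge overlap count; abutting and opposite-strand do not
        assert out.reads_all.tolist() == [2]
        assert out.attrs["total_reads"] == {"all": 4}


@pytest.fixture(scope="module")
def mixed_biotype_index(tmp_path_factory):
    gtf = tmp_path_factory.mktemp("anno") / "mix.gtf"
    pc = 'gene_id "PC1"; transcript_id "PC1.1"; gene_biotype "protein_coding";'
    nc = 'gene_id "NC1"; transcript_id "NC1.1"; gene_biotype "lncRNA";'
    lines = [
        # coding gene: exon1 [100,300) with CDS [200,300), exon2 [500,700)
        # with CDS [500,600) -> 5UTR [100,200), 3UTR [600,700)
        f"chr1\tx\texon\t101\t300\t.\t+\t.\t{pc}",
        f"chr1\tx\tCDS\t201\t300\t.\t+\t.\t{pc}",
        f"chr1\tx\texon\t501\t700\t.\t+\t.\t{pc}",
        f"chr1\tx\tCDS\t501\t600\t.\t+\t.\t{pc}",
        # lncRNA overlapping the coding gene's intron and beyond
        f"chr1\tx\texon\t251\t1000\t.\t+\t.\t{nc}",
    ]
    gtf.write_text("\n".join(lines) + "\n")
    return build_annotation_index(gtf)


class TestAnnotatePeak:
    @pytest.mark.parametrize(
        "interval,expected",
        [
            ((250, 280), "CDS"),  # CDS beats overlapping lncRNA exon
            ((120, 150), "5UTR"),
            ((620, 680), "3UTR"),
            ((350, 400), "pc_intron"),  # pc intron beats lncRNA exon
            ((750, 900), "nc_exon"),
            ((5000, 5100), "intergenic"),
        ],
    )
    def test_priority_hierarchy(self, mixed_biotype_index, interval, expected):
        assert clip.annotate_peak(mixed_biotype_index, "chr1", *interval, "+") == expected


class TestBindingOverlap:
    def test_reported_set_sizes_solve_shared_and_union(self):
        ov = clip.BindingOverlap.from_counts(5143, 4354, a_only=1260, b_only=471)
        assert ov.shared == 3883 and ov.union == 5614
        assert round(ov.fraction_of_union("shared"), 1) == 69.2
        assert round(ov.fraction_of_union("a_only"), 1) == 22.4

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            clip.BindingOverlap.from_counts(100, 90, a_only=10, b_only=10)

    def test_disjoint_and_identical_sets(self):
        disjoint = clip.binding_overlap({"a", "b"}, {"c"})
        assert disjoint.shared == 0
        assert disjoint.fraction_of_union("a_only") + disjoint.fraction_of_union(
            "b_only"
        ) == pytest.approx(100.0)
        same = clip.binding_overlap({"a", "b"}, {"a", "b"})
        assert same.fraction_of_union("shared") == pytest.approx(100.0)

    @given(
        a=st.sets(st.integers(0, 60), max_size=40),
        b=st.sets(st.integers(0, 60), max_size=40),
    )
    def test_identities_hold_for_all_inputs(self, a, b):
        ov = clip.binding_overlap(a, b)
        assert ov.union == ov.a_only + ov.b_only + ov.shared
        assert ov.size_a == ov.a_only + ov.shared
        assert ov.size_b == ov.b_only + ov.shared
        if ov.union:
            total = sum(ov.fraction_of_union(p) for p in ("a_only", "b_only", "shared"))
            assert total == pytest.approx(100.0)
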