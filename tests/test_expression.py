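"""QC filters, DEG presets, signature scoring, quadrant overlap, rescue calls."""

import anndata as ad
import numpy as np
import pandas as pd
import pytest

from crypticflow import expression as ex
from crypticflow.simulate import CellSimSpec, simulate_cells


def make_adata(X, mito=None, genes=None, cells=None):
    X = np.asarray(X, dtype=float)
    n_cells, n_genes = X.shape
    genes = genes or [f"g{j}" for j in range(n_genes)]
    cells = cells or [f"c{i}" for i in range(n_cells)]
    var = pd.DataFrame({"mito": mito or [False] * n_genes}, index=genes)
    return ad.AnnData(X=X, obs=pd.DataFrame(index=cells), var=var)


class TestQcFilter:
    def test_gene_expressed_in_exactly_five_cells_removed(self):
        # 20 cells; gene0 expressed in 5 cells (dropped), gene1 in 6 (kept);
        # the remaining genes keep every cell above the detection threshold
        X = np.ones((20, 300))
        X[:, 0] = 0
        X[:5, 0] = 1
        X[:, 1] = 0
        X[:6, 1] = 1
        adata = make_adata(X)
        filt, report = ex.qc_filter(adata, min_genes_per_cell=100)
        assert "g0" not in filt.var_names and "g1" in filt.var_names
        assert report["genes_removed"] == 1

    def test_cell_detection_boundary(self):
        # 250 genes all passing the gene filter; cell0 detects 199, cell1 200
        X = np.ones((20, 250))
        X[0, 199:] = 0
        X[1, 200:] = 0
        filt, _ = ex.qc_filter(make_adata(X))
        assert "c0" not in filt.obs_names and "c1" in filt.obs_names

    def test_mito_fraction_boundary_inclusive_removal(self):
        # cell0 at exactly 10% mitochondrial -> removed; cell1 below -> kept
        X = np.ones((20, 250))
        mito = [True] * 25 + [False] * 225
        X[:, :25] = 0.2  # baseline cells ~2% mitochondrial
        X[0, :25] = 1.0  # 25 / 250 = exactly 10%
        X[1, :25] = 0.5  # ~5%
        filt, report = ex.qc_filter(make_adata(X, mito=mito))
        assert "c0" not in filt.obs_names and "c1" in filt.obs_names
        assert report["cells_removed_high_mito"] == 1

    def test_idempotent(self):
        adata = simulate_cells(CellSimSpec(seed=13))
        once, _ = ex.qc_filter(adata)
        twice, report = ex.qc_filter(once)
        assert twice.shape == once.shape
        assert report["genes_removed"] == 0
        assert report["cells_removed_low_genes"] == report["cells_removed_high_mito"] == 0

    def test_all_cells_removed_is_error(self):
        X = np.zeros((10, 250))
        X[:, :8] = 1  # every cell detects only 8 genes
        with pytest.raises(ValueError, match="every cell"):
            ex.qc_filter(make_adata(X))


class TestThresholdDeg:
    records = pd.DataFrame(
        {
            "gene": ["a", "b", "c", "d", "e"],
            "log2fc": [1.5, 1.0, -2.0, 0.5, 1.2],
            "padj": [0.01, 0.01, 0.001, 0.001, 0.06],
            "pct": [0.5, 0.5, 0.5, 0.5, 0.5],
        }
    )

    def test_bulk_preset_strict_fold_change(self):
        out = ex.threshold_deg(self.records, preset="bulk")
        assert set(out.gene) == {"a", "c"}  # |log2FC| > 1 strict; padj < 0.05
        assert dict(zip(out.gene, out.direction)) == {"a": "up", "c": "down"}

    def test_marker_preset_inclusive_and_up_only(self):
        out = ex.threshold_deg(self.records, preset="marker")
        assert set(out.gene) == {"a", "b"}  # log2FC >= 1 inclusive, signed

    def test_marker_preset_pct_floor(self):
        rec = self.records.assign(pct=[0.5, 0.09, 0.5, 0.5, 0.5])
        assert set(ex.threshold_deg(rec, preset="marker").gene) == {"a"}

    def test_unknown_preset(self):
        with pytest.raises(ValueError):
            ex.threshold_deg(self.records, preset="nope")


class TestSignature:
    def test_printed_boundaries(self):
        rec = pd.DataFrame(
            {
                "gene": ["in1", "in_fc4", "low_pct", "high_p", "low_fc"],
                "pct": [0.25, 0.20, 0.19, 0.25, 0.25],
                "padj": [0.01, 0.049, 0.01, 0.05, 0.01],
                "fold_change": [5.0, 4.0, 5.0, 5.0, 3.9],
            }
        )
        assert ex.define_signature(rec) == ["in1", "in_fc4"]

    def test_log2fc_column_converted_to_linear(self):
        rec = pd.DataFrame(
            {"gene": ["x", "y"], "pct": [0.5, 0.5], "padj": [0.01, 0.01], "log2fc": [2.0, 1.9]}
        )
        assert ex.define_signature(rec) == ["x"]  # 2^2 = 4 >= 4; 2^1.9 < 4

    def test_empty_signature_warns(self):
        rec = pd.DataFrame({"gene": ["x"], "pct": [0.0], "padj": [1.0], "fold_change": [1.0]})
        with pytest.warns(UserWarning):
            assert ex.define_signature(rec) == []


class TestScoreSignature:
    def test_mean_of_signature_rows(self):
        adata = make_adata([[2, 4, 100], [0, 0, 5]])
        scores = ex.score_signature(adata, ["g0", "g1"], normalize=False)
        assert scores.tolist() == [3.0, 0.0]

    def test_missing_genes_dropped_with_warning(self):
        adata = make_adata([[2, 4, 0]])
        with pytest.warns(UserWarning, match="not in matrix"):
            scores = ex.score_signature(adata, ["g0", "absent"], normalize=False)
        assert scores.tolist() == [2.0]
        with pytest.raises(ValueError):
            ex.score_signature(adata, ["absent"])

    def test_linear_in_disjoint_signature_union(self):
        rng = np.random.default_rng(14)
        adata = make_adata(rng.poisson(5, size=(30, 40)))
        sig_a = [f"g{j}" for j in range(10)]
        sig_b = [f"g{j}" for j in range(10, 25)]
        both = ex.score_signature(adata, sig_a + sig_b)
        weighted = (10 * ex.score_signature(adata, sig_a) + 15 * ex.score_signature(adata, sig_b)) / 25
        assert np.allclose(both, weighted)

    def test_planted_signature_recovered(self):
        adata = simulate_cells(CellSimSpec(signature_log2fc=2.0, seed=15))
        sig = list(adata.var_names[adata.var.signature])
        scores = ex.score_signature(adata, sig)
        planted = adata.obs.planted.to_numpy()
        diff = scores[planted].mean() - scores[~planted].mean()
        se = np.sqrt(
            scores[planted].var() / planted.sum() + scores[~planted].var() / (~planted).sum()
        )
        assert diff > 3 * se


class TestQuadrant:
    @staticmethod
    def fixture_tables():
        """DE pair encoding the published overlap counts: axis B has 178 up
        and 153 down genes; axis A shares 177 of the ups and 9 of the downs."""
        up = [f"U{i}" for i in range(178)]
        down = [f"D{i}" for i in range(153)]
        b = pd.DataFrame(
            {"gene": up + down, "log2fc": [2.0] * 178 + [-2.0] * 153, "padj": 0.001}
        )
        a_rows = (
            [(g, 2.0, 0.001) for g in up[:177]]
            + [(up[177], 0.1, 0.9)]
            + [(g, -2.0, 0.001) for g in down[:9]]
            + [(g, 0.0, 0.9) for g in down[9:]]
        )
        a = pd.DataFrame(a_rows, columns=["gene", "log2fc", "padj"])
        return a, b

    def test_overlap_percentages_reproduce_count_arithmetic(self):
        a, b = self.fixture_tables()
        res = ex.quadrant_analysis(a, b)
        assert res.counts["Q1"] == 177 and res.counts["Q3"] == 9
        assert round(res.overlap["pct_of_b_up"], 1) == 99.4
        assert round(res.overlap["pct_of_b_down"], 1) == 5.9

    def test_counts_partition_classified_genes(self):
        a, b = self.fixture_tables()
        res = ex.quadrant_analysis(a, b)
        assert sum(res.counts.values()) == len(res.table)

    def test_empty_axis_yields_zero_quadrants(self):
        _, b = self.fixture_tables()
        a = b.assign(padj=1.0)  # nothing significant on axis A
        res = ex.quadrant_analysis(a, b)
        assert res.counts["Q1"] == res.counts["Q3"] == 0

    def test_disjoint_namespaces_rejected(self):
        a = pd.DataFrame({"gene": ["x"], "log2fc": [2.0], "padj": [0.01]})
        b = pd.DataFrame({"gene": ["y"], "log2fc": [2.0], "padj": [0.01]})
        with pytest.raises(ValueError, match="no genes"):
            ex.quadrant_analysis(a, b)


class TestRescue:
    untreated = pd.DataFrame(
        {"gene": ["a", "b", "c", "d"], "log2fc": [3.0, 1.0, -3.0, 2.0], "padj": [0.01, 0.01, 0.01, 0.2]}
    )

    def test_rule_application(self):
        treated = pd.DataFrame({"gene": ["a", "b", "c", "d"], "log2fc": [1.0, 3.0, -1.0, 0.5]})
        res = ex.classify_rescue(self.untreated, treated).set_index("gene")
        assert bool(res.loc["a", "rescued"])  # 3 -> 1
        assert not bool(res.loc["b", "rescued"])  # 1 -> 3, worse
        assert bool(res.loc["c", "rescued"])  # |-3| -> |-1| under absolute mode
        assert not bool(res.loc["d", "rescued"])  # untreated p >= 0.05

    def test_equal_fold_change_not_rescued(self):
        treated = pd.DataFrame({"gene": ["a"], "log2fc": [3.0]})
        res = ex.classify_rescue(self.untreated, treated).set_index("gene")
        assert not bool(res.loc["a", "rescued"])

    def test_missing_gene_unclassified(self):
        treated = pd.DataFrame({"gene": ["a"], "log2fc": [1.0]})
        res = ex.classify_rescue(self.untreated, treated).set_index("gene")
        assert pd.isna(res.loc["b", "rescued"])
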