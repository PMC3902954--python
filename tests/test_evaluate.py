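import numpy as np
import pandas as pd
import pytest

from trapfe.catalog import CODING, LONG_NONCODING, SHORT_NONCODING
from trapfe.evaluate import (
    EnrichmentCall,
    call_enriched,
    cross_classify,
    de_fraction_by_stratum,
    fc_histogram,
    jaccard,
    length_fc_regression,
    organ_marker_sets,
    threshold_sweep,
    truth_metrics,
    venn_compare,
)

from conftest import make_catalog


def de_frame(fc, padj, genes=None):
    fc = np.asarray(fc, dtype=float)
    genes = genes or [f"g{i}" for i in range(len(fc))]
    with np.errstate(divide="ignore"):
        log2fc = np.log2(fc)
    return pd.DataFrame(
        {
            "base_mean_A": np.ones_like(fc),
            "base_mean_B": fc,
            "fold_change": fc,
            "log2fc": log2fc,
            "pval": np.asarray(padj, dtype=float),
            "padj": np.asarray(padj, dtype=float),
        },
        index=pd.Index(genes, name="gene_id"),
    )


def series(values, genes=None):
    genes = genes or [f"g{i}" for i in range(len(values))]
    return pd.Series(values, index=genes)


class TestCallEnriched:
    def test_passing_and_failing_thresholds(self):
        de = de_frame([3.0], [1e-5])
        assert call_enriched(de, series([10.0])).genes == ["g0"]
        assert call_enriched(de_frame([3.0], [0.01]), series([10.0])).genes == []

    def test_six_gene_worked_table_with_infinite_fc(self):
        de = de_frame(
            [3.0, 3.0, np.inf, 1.5, 5.0, 4.0],
            [1e-5, 0.01, 1e-6, 1e-5, 1e-4, 1e-5],
        )
        rpkm = series([10.0, 10.0, 5.0, 8.0, 0.5, 2.0])
        call = call_enriched(de, rpkm, fc_min=2.0, padj_max=0.001,
                             rpkm_floor=1.0)
        assert call.genes == ["g0", "g2", "g5"]

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            call_enriched(de_frame([2.0], [0.5]), series([1.0]), fc_min=-1)


class TestVenn:
    def make(self, genes):
        return EnrichmentCall(genes, "transcriptome", 2.0, 0.001, 1.0)

    def test_identical_disjoint_and_overlapping(self):
        a = self.make(["a", "b", "c"])
        assert venn_compare(a, a)["both"] == 3
        d = venn_compare(a, self.make(["x", "y"]))
        assert (d["only_a"], d["both"], d["only_b"]) == (3, 0, 2)
        d = venn_compare(a, self.make(["b", "c", "d"]))
        assert (d["only_a"], d["both"], d["only_b"]) == (1, 2, 1)
        assert jaccard(a, self.make(["b", "c", "d"])) == pytest.approx(0.5)


class TestCrossClassify:
    def test_eight_gene_worked_table(self):
        call = EnrichmentCall([f"g{i}" for i in range(8)], "transcriptome",
                              2.0, 0.001, 1.0)
        de_tl = pd.DataFrame(
            {
                "log2fc": [1, -2, 0.5, 3, -1, 0.2, 4, -3],
                "padj": [1e-4, 1e-4, 0.5, 1e-5, 1e-6, 0.9, 0.2, 1e-4],
            },
            index=[f"g{i}" for i in range(8)],
        )
        cc = cross_classify(call, de_tl)
        assert cc.enriched == ["g0", "g3"]
        assert cc.depleted == ["g1", "g4", "g7"]
        assert cc.not_significant == ["g2", "g5", "g6"]
        assert cc.counts == {"enriched": 2, "not_significant": 3, "depleted": 3}

    def test_categories_partition_input(self, rng):
        genes = [f"g{i}" for i in range(50)]
        call = EnrichmentCall(genes, "transcriptome", 2.0, 0.001, 1.0)
        de_tl = pd.DataFrame(
            {
                "log2fc": rng.normal(size=50),
                "padj": rng.uniform(size=50),
            },
            index=genes,
        )
        cc = cross_classify(call, de_tl)
        combined = cc.enriched + cc.not_significant + cc.depleted
        assert sorted(combined) == sorted(genes)

    def test_insignificant_gene_never_classified_by_fc(self):
        call = EnrichmentCall(["g0"], "transcriptome", 2.0, 0.001, 1.0)
        de_tl = pd.DataFrame({"log2fc": [5.0], "padj": [0.5]}, index=["g0"])
        assert cross_classify(call, de_tl).not_significant == ["g0"]

    def test_missing_genes_rejected(self):
        call = EnrichmentCall(["gX"], "transcriptome", 2.0, 0.001, 1.0)
        de_tl = pd.DataFrame({"log2fc": [1.0], "padj": [0.1]}, index=["g0"])
        with pytest.raises(ValueError, match="missing"):
            cross_classify(call, de_tl)


class TestThresholdSweep:
    def toy_tables(self):
        de_tx = de_frame(
            [1.5, 2.5, 3.0, 5.0, np.inf, 0.5, 8.0, 2.1, 4.5, 1.2],
            [1e-5] * 10,
        )
        de_tl = pd.DataFrame(
            {
                "log2fc": [0.1, 2.0, 0.3, 2.0, 0.0, 0.0, -1.0, -2.0, 1.5, 0.2],
                "padj": [0.5, 1e-5, 0.5, 1e-5, 0.5, 0.5, 1e-4, 1e-4, 1e-5, 0.5],
            },
            index=[f"g{i}" for i in range(10)],
        )
        return de_tx, de_tl, series([10.0] * 10)

    def test_hand_sweep(self):
        de_tx, de_tl, rpkm = self.toy_tables()
        sweep = threshold_sweep(de_tx, de_tl, rpkm, tau_grid=(1.0, 2.0, 4.0))
        assert sweep["total"].tolist() == [9, 7, 4]
        assert sweep["confirmed_enriched"].tolist() == [3, 3, 2]
        assert sweep["depleted"].tolist() == [2, 2, 1]
        assert sweep["not_significant"].tolist() == [4, 2, 1]

    def test_low_tau_equals_unthresholded_cross_classification(self):
        de_tx, de_tl, rpkm = self.toy_tables()
        sweep = threshold_sweep(de_tx, de_tl, rpkm, tau_grid=(0.1,))
        call = call_enriched(de_tx, rpkm, fc_min=0.1)
        cc = cross_classify(call, de_tl)
        assert sweep.loc[0, "total"] == cc.n_total
        assert sweep.loc[0, "confirmed_enriched"] == len(cc.enriched)

    def test_tau_above_max_finite_fc_keeps_only_infinite(self):
        de_tx, de_tl, rpkm = self.toy_tables()
        finite = de_tx[np.isfinite(de_tx["fold_change"])]
        sweep = threshold_sweep(finite, de_tl, rpkm, tau_grid=(100.0,))
        assert sweep.loc[0, "total"] == 0
        # the infinite-FC gene survives any threshold
        sweep_inf = threshold_sweep(de_tx, de_tl, rpkm, tau_grid=(100.0,))
        assert sweep_inf.loc[0, "total"] == 1

    def test_counts_non_increasing_in_tau(self, rng):
        genes = [f"g{i}" for i in range(200)]
        de_tx = de_frame(rng.lognormal(0, 1.5, size=200),
                         rng.uniform(size=200) ** 3, genes)
        de_tl = pd.DataFrame(
            {"log2fc": rng.normal(size=200), "padj": rng.uniform(size=200)},
            index=genes,
        )
        sweep = threshold_sweep(de_tx, de_tl, series([10.0] * 200, genes),
                                tau_grid=tuple(np.logspace(0, 1.5, 15)))
        assert (np.diff(sweep["total"]) <= 0).all()
        assert (np.diff(sweep["confirmed_enriched"]) <= 0).all()

    def test_bad_grids_rejected(self):
        de_tx, de_tl, rpkm = self.toy_tables()
        with pytest.raises(ValueError):
            threshold_sweep(de_tx, de_tl, rpkm, tau_grid=())
        with pytest.raises(ValueError):
            threshold_sweep(de_tx, de_tl, rpkm, tau_grid=(2.0, 1.0))


class TestOrganMarkers:
    def test_six_gene_worked_table(self):
        de_between = de_frame(
            [10.0, 3.9, 5.0, 4.0, 6.0, 8.0],
            [1e-5, 1e-5, 1e-5, 1e-5, 1e-5, 0.01],
        )
        de_ref = de_frame(
            [3.0, 5.0, 1.9, 2.0, 3.0, 4.0],
            [1e-5] * 6,
        )
        rpkm = series([20.0, 30.0, 10.0, 5.0, 4.0, 6.0])
        call = organ_marker_sets(de_between, de_ref, rpkm)
        assert call.genes == ["g0", "g3"]

    def test_at_least_semantics_include_exact_threshold(self):
        de_between = de_frame([4.0], [1e-5])
        de_ref = de_frame([2.0], [1e-5])
        assert organ_marker_sets(de_between, de_ref, series([5.0])).genes == ["g0"]

    def test_misaligned_tables_rejected(self):
        with pytest.raises(ValueError, match="aligned"):
            organ_marker_sets(
                de_frame([4.0], [1e-5]),
                de_frame([2.0], [1e-5], genes=["other"]),
                series([5.0]),
            )


class TestTruthMetrics:
    def make(self, genes):
        return EnrichmentCall(genes, "transcriptome", 2.0, 0.001, 1.0)

    def test_perfect_call(self):
        truth = series([True, True, False, False])
        m = truth_metrics(self.make(["g0", "g1"]), truth)
        assert m.sensitivity == 1.0 and m.fdr == 0.0 and m.specificity == 1.0

    def test_empty_call(self):
        truth = series([True, False])
        m = truth_metrics(self.make([]), truth)
        assert m.sensitivity == 0.0 and m.fdr == 0.0

    def test_ten_gene_confusion_table(self):
        truth = series([True] * 4 + [False] * 6)
        m = truth_metrics(self.make(["g0", "g1", "g2", "g4", "g5"]), truth)
        assert (m.tp, m.fp, m.fn, m.tn) == (3, 2, 1, 4)
        assert m.sensitivity == pytest.approx(0.75)
        assert m.fdr == pytest.approx(0.4)
        assert m.specificity == pytest.approx(4 / 6)


class TestStratumFractions:
    def test_all_significant_or_none(self):
        de = de_frame([2.0] * 6, [1.0] * 6)
        rpkm = series([0.5, 0.5, 3.0, 3.0, 10.0, 10.0])
        out = de_fraction_by_stratum(de, rpkm, edges=(1.0, 5.0))
        assert (out["fraction_significant"] == 0).all()
        de0 = de_frame([2.0] * 6, [0.0] * 6)
        out0 = de_fraction_by_stratum(de0, rpkm, edges=(1.0, 5.0))
        assert (out0["fraction_significant"] == 1).all()

    def test_twelve_gene_worked_table(self):
        # strata: 4 genes below 1 RPKM (1 sig), 4 in (1,5] (2 sig),
        # 4 above 5 (3 sig)
        padj = [1e-4, 1, 1, 1, 1e-4, 1e-4, 1, 1, 1e-4, 1e-4, 1e-4, 1]
        rpkm = series([0.5] * 4 + [2.0] * 4 + [10.0] * 4)
        out = de_fraction_by_stratum(de_frame([2.0] * 12, padj), rpkm,
                                     edges=(1.0, 5.0))
        np.testing.assert_allclose(
            out["fraction_significant"], [0.25, 0.5, 0.75]
        )
        assert out["n_genes"].tolist() == [4, 4, 4]

    def test_empty_stratum_is_nan_not_zero(self):
        de = de_frame([2.0, 2.0], [0.5, 0.5])
        out = de_fraction_by_stratum(de, series([0.5, 0.6]), edges=(1.0, 5.0))
        assert np.isnan(out.loc[1, "fraction_significant"])
        assert np.isnan(out.loc[2, "fraction_significant"])


class TestFCHistogram:
    def test_single_gene_single_bin(self):
        catalog = make_catalog([1000])
        out = fc_histogram(de_frame([2.0], [0.5]), catalog,
                           bin_edges=np.array([0.0, 2.0]))
        assert out["count"].tolist() == [1]

    def test_symmetric_fold_changes_mirror(self):
        catalog = make_catalog([1000] * 4)
        de = de_frame(2.0 ** np.array([1.5, -1.5, 0.5, -0.5]), [0.5] * 4)
        out = fc_histogram(de, catalog, bin_edges=np.linspace(-3, 3, 7))
        counts = out["count"].to_numpy()
        np.testing.assert_array_equal(counts, counts[::-1])

    def test_infinite_fcs_in_outermost_bins_and_biotype_filter(self):
        catalog = make_catalog(
            [1000] * 4,
            biotypes=[CODING, CODING, SHORT_NONCODING, LONG_NONCODING],
        )
        de = de_frame([np.inf, 1.0, 0.0, 2.0], [0.5] * 4)
        out = fc_histogram(de, catalog, bin_edges=np.linspace(-2, 2, 5))
        assert out["count"].sum() == 4
        assert out["count"].iloc[-1] >= 1  # +inf in top bin
        assert out["count"].iloc[0] >= 1  # -inf (fc=0) in bottom bin
        coding_only = fc_histogram(de, catalog, biotypes=(CODING,),
                                   bin_edges=np.linspace(-2, 2, 5))
        assert coding_only["count"].sum() == 2


class TestLengthRegression:
    def test_exact_line_recovered(self):
        lengths = [100, 1000, 10_000, 100_000]
        catalog = make_catalog(lengths)
        lfc = -1.0 * np.log10(lengths) + 2.0
        de = de_frame(2.0 ** lfc, [0.5] * 4)
        slope, intercept, r = length_fc_regression(de, catalog)
        assert slope == pytest.approx(-1.0)
        assert intercept == pytest.approx(2.0)
        assert r == pytest.approx(-1.0)

    def test_constant_fc_gives_zero_slope(self):
        catalog = make_catalog([100, 1000, 10_000])
        de = de_frame([2.0, 2.0, 2.0], [0.5] * 3)
        slope, _, r = length_fc_regression(de, catalog)
        assert slope == 0.0 and r == 0.0

    def test_too_few_finite_genes_rejected(self):
        catalog = make_catalog([100, 1000, 10_000])
        de = de_frame([2.0, np.inf, 0.0], [0.5] * 3)
        with pytest.raises(ValueError, match="at least 3"):
            length_fc_regression(de, catalog)
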