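import numpy as np
import pandas as pd
import pytest
from scipy import stats

from bivalint import diffexpr as de
from bivalint import synthetic_data as sd
from conftest import make_expt


class TestFilterLowCounts:
    def test_all_zero_gene_removed(self):
        expt = make_expt(np.vstack([np.zeros(12), np.full(12, 5)]))
        out = de.filter_low_counts(expt)
        assert list(out.genes) == ["G1"]

    def test_mean_exactly_one_retained(self):
        counts = np.ones((1, 12), dtype=int)
        out = de.filter_low_counts(make_expt(counts))
        assert len(out.genes) == 1

    def test_total_eleven_of_twelve_removed(self):
        counts = np.zeros((1, 12), dtype=int)
        counts[0, :11] = 1  # total 11 < 12
        out = de.filter_low_counts(make_expt(counts))
        assert len(out.genes) == 0


class TestSizeFactors:
    def test_identical_samples_all_one(self):
        expt = make_expt(np.tile([[10], [20], [30]], (1, 12)))
        assert np.allclose(de.size_factors(expt), 1.0)

    def test_doubled_sample_hand_oracle(self):
        # sample2 = 2 x sample1: factors are (1/sqrt(2), sqrt(2))
        counts = np.array([[10, 20], [50, 100], [7, 14]])
        expt = make_expt(counts, n_reps=1)
        sf = de.size_factors(expt)
        assert np.allclose(sf.values, [2**-0.5, 2**0.5], atol=1e-9)

    def test_all_zero_sample_rejected(self):
        counts = np.array([[5, 0], [9, 0]])
        with pytest.raises(ValueError, match="nonzero"):
            de.size_factors(make_expt(counts, n_reps=1))

    def test_gene_order_invariance_and_scaling_equivariance(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(50, (30, 12))
        expt = make_expt(counts)
        sf = de.size_factors(expt)
        perm = rng.permutation(30)
        sf_perm = de.size_factors(make_expt(counts[perm]))
        assert np.allclose(sf, sf_perm)
        # doubling one library doubles its factor relative to the rest
        scaled = counts.copy()
        scaled[:, 0] *= 2
        sf2 = de.size_factors(make_expt(scaled))
        ratio = (sf2 / sf).values
        assert ratio[0] / ratio[1] == pytest.approx(2.0, rel=1e-6)


class TestFitContrast:
    def test_unknown_contrast_rejected(self, default_fit):
        with pytest.raises(ValueError, match="unknown contrast"):
            default_fit.contrast("nope")

    def test_identical_cells_give_zero_lfc_p_one(self):
        block = np.tile([[8, 12, 10]], (1, 4))  # same 3 values in every cell
        counts = np.vstack([block, np.tile([[100, 90, 110]], (1, 4))])
        fit = de.FactorialFit(make_expt(counts))
        res = fit.contrast("e2_vs_ctrl")
        assert res.table["log2fc"].iloc[0] == 0.0
        assert res.table["pvalue"].iloc[0] == 1.0

    def test_null_type_one_error_calibrated(self):
        truth, _ = sd.generate_truth(2000, class_fractions={}, seed=11)
        expt = sd.generate_counts(truth, n_reps=3, seed=12)
        fit = de.FactorialFit(de.filter_low_counts(expt))
        frac = (fit.contrast("e2_vs_ctrl").table["pvalue"] < 0.05).mean()
        assert 0.03 <= frac <= 0.07

    def test_planted_lfc_recovered(self):
        truth, _ = sd.generate_truth(
            2000, class_fractions={"coop-up": 0.05, "coop-down": 0.05},
            lfc_range=(2.0, 2.0), seed=5,
        )
        expt = sd.generate_counts(truth, n_reps=3, seed=6)
        res = de.FactorialFit(de.filter_low_counts(expt)).contrast("e2_vs_ctrl")
        t = truth.table
        planted = [
            g for g in t.index[(t["effect_class"] == "coop-up") & (t["base_mean"] >= 100)]
            if g in res.genes
        ]
        assert abs(res.table.loc[planted, "log2fc"].median() - 2.0) <= 0.25

    def test_wald_stat_equals_lfc_over_se(self, default_fit):
        res = default_fit.contrast("interaction")
        t = res.table[res.table["se"] > 0]
        assert np.allclose(np.abs(t["wald_stat"]), np.abs(t["log2fc"] / t["se"]))


class TestWeightedFdr:
    def test_single_bin_is_plain_bh_hand_oracle(self):
        p = np.array([0.01, 0.02, 0.03, 0.04])
        q = de.weighted_fdr(p, np.arange(4.0), n_bins=1)
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_uniform_null_rejection_bounded(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=2000)
        cov = rng.lognormal(5, 1, 2000)
        q = de.weighted_fdr(p, cov, n_bins=5, alpha=0.05)
        se = np.sqrt(0.05 * 0.95 / 2000)
        assert (q < 0.05).mean() <= 0.05 + 3 * se

    def test_informative_covariate_beats_plain_bh(self):
        # signal concentrated in the top covariate bin: weighting must not
        # reject fewer hypotheses than plain BH (the point of IHW)
        rng = np.random.default_rng(4)
        n = 2000
        cov = np.sort(rng.lognormal(5, 1, n))
        p = rng.uniform(size=n)
        effect = slice(int(0.9 * n), n)
        p[effect] = rng.beta(0.08, 1.0, n - int(0.9 * n))
        alpha = 0.1
        q_plain = de.weighted_fdr(p, cov, n_bins=1, alpha=alpha)
        q_w = de.weighted_fdr(p, cov, n_bins=5, alpha=alpha)
        assert (q_w < alpha).sum() >= (q_plain < alpha).sum()

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            de.weighted_fdr(np.array([0.5, 1.5]), np.array([1.0, 2.0]))

    def test_qvalues_monotone_in_p_within_bin(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(size=500)
        cov = rng.normal(size=500)
        q = de.weighted_fdr(p, cov, n_bins=5, alpha=0.05)
        ranks = stats.rankdata(cov, method="ordinal")
        bins = np.minimum(((ranks - 1) * 5) // 500, 4).astype(int)
        for b in range(5):
            sel = bins == b
            order = np.argsort(p[sel])
            assert (np.diff(q[sel][order]) >= -1e-12).all()


class TestRlogAndVariableGenes:
    def test_zero_count_maps_to_two(self):
        expt = make_expt(np.zeros((1, 12), dtype=int))
        sf = pd.Series(1.0, index=expt.samples)
        assert np.allclose(de.rlog_like(expt, sf), 2.0)

    def test_doubling_large_counts_adds_one(self):
        expt = make_expt(np.array([[10_000] * 12, [20_000] * 12]))
        sf = pd.Series(1.0, index=expt.samples)
        m = de.rlog_like(expt, sf)
        assert m.iloc[1, 0] - m.iloc[0, 0] == pytest.approx(1.0, abs=1e-3)

    def test_monotone_in_counts(self):
        expt = make_expt(np.arange(12).reshape(1, 12))
        sf = pd.Series(1.0, index=expt.samples)
        assert (np.diff(de.rlog_like(expt, sf).to_numpy()[0]) > 0).all()

    def test_constant_gene_excluded_everywhere(self):
        mat = pd.DataFrame([[5.0] * 6, [1, 2, 3, 4, 5, 6]], index=["flat", "vary"])
        assert "flat" not in de.select_variable_genes(mat, min_variance=0.001)
        assert de.select_variable_genes(mat, min_variance=None, top_n=1) == ["vary"]

    def test_top_n_exact_count_sorted_by_variance(self):
        rng = np.random.default_rng(1)
        mat = pd.DataFrame(rng.normal(size=(2000, 6)) * rng.uniform(0.1, 3, (2000, 1)))
        mat.index = [f"g{i}" for i in range(2000)]
        top = de.select_variable_genes(mat, min_variance=None, top_n=500)
        assert len(top) == 500
        var = mat.var(axis=1)
        assert set(top) == set(var.sort_values(ascending=False).index[:500])

    def test_threshold_is_strict(self):
        mat = pd.DataFrame([[0.0, 2.0]], index=["g"])  # variance exactly 2
        assert de.select_variable_genes(mat, min_variance=2.0) == []
        assert de.select_variable_genes(mat, min_variance=1.999) == ["g"]

    def test_mode_selection_errors(self):
        mat = pd.DataFrame([[1.0, 2.0]])
        with pytest.raises(ValueError):
            de.select_variable_genes(mat, min_variance=0.1, top_n=5)
        with pytest.raises(ValueError):
            de.select_variable_genes(mat, min_variance=None, top_n=None)


class TestPca:
    def test_identical_samples_identical_coordinates(self):
        rng = np.random.default_rng(2)
        col = rng.normal(size=20)
        mat = pd.DataFrame(
            np.column_stack([col, col, rng.normal(size=20)]), columns=["a", "b", "c"]
        )
        coords, _ = de.pca(mat, top_n=None)
        assert np.allclose(coords.loc["a"], coords.loc["b"], atol=1e-8)

    def test_explained_variance_non_increasing_and_bounded(self):
        rng = np.random.default_rng(3)
        mat = pd.DataFrame(rng.normal(size=(50, 8)))
        _, ev = de.pca(mat, top_n=None)
        assert (np.diff(ev) <= 1e-12).all()
        assert ev.sum() <= 1 + 1e-9

    def test_design_cells_separate_with_strong_effects(self):
        from sklearn.metrics import silhouette_score

        truth, _ = sd.generate_truth(
            500,
            class_fractions={"coop-up": 0.15, "coop-down": 0.1, "antag-up": 0.1},
            lfc_range=(2.0, 3.0), seed=13,
        )
        expt = sd.generate_counts(truth, n_reps=3, seed=14)
        sf = de.size_factors(expt)
        coords, _ = de.pca(de.rlog_like(expt, sf), top_n=200)
        labels = expt.cell_labels().values
        assert silhouette_score(coords.iloc[:, :2], labels) > 0.5

    def test_too_few_genes_rejected(self):
        with pytest.raises(ValueError, match="genes"):
            de.pca(pd.DataFrame([[1.0, 2.0]]), top_n=None)
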