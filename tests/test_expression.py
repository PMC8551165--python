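"""Normalization, NB differential expression, PCA, PERMANOVA, paired t-test."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from holosym import expression, simulate


def reference_bh(pvals):
    """Independent Benjamini-Hochberg implementation (step-up, from the back)."""
    p = np.asarray(pvals, dtype=float)
    n = len(p)
    order = np.argsort(p)
    adj = np.empty(n)
    running_min = 1.0
    for rank_from_end, idx in enumerate(order[::-1]):
        rank = n - rank_from_end
        running_min = min(running_min, p[idx] * n / rank)
        adj[idx] = running_min
    return adj


class TestFilterLowCounts:
    def test_boundary(self):
        counts = pd.DataFrame({"s1": [5, 4, 0], "s2": [5, 5, 0]},
                              index=["keep", "drop", "zero"])
        out = expression.filter_low_counts(counts, min_total=10)
        assert list(out.index) == ["keep"]

    def test_matches_row_sum_oracle(self, rng):
        counts = pd.DataFrame(rng.integers(0, 8, (50, 6)),
                              index=[f"g{i}" for i in range(50)],
                              columns=[f"s{i}" for i in range(6)])
        out = expression.filter_low_counts(counts, min_total=10)
        expected = [g for g in counts.index if counts.loc[g].sum() >= 10]
        assert list(out.index) == expected

    def test_all_removed_raises(self):
        counts = pd.DataFrame({"s1": [1], "s2": [2]}, index=["g"])
        with pytest.raises(ValueError):
            expression.filter_low_counts(counts, min_total=10)


class TestSizeFactors:
    def test_identical_columns(self):
        counts = pd.DataFrame({"a": [3, 7, 11], "b": [3, 7, 11], "c": [3, 7, 11]})
        assert np.allclose(expression.size_factors(counts), 1.0)

    def test_doubled_column(self):
        counts = pd.DataFrame({"a": [4, 10, 20], "b": [4, 10, 20], "c": [8, 20, 40]})
        s = expression.size_factors(counts)
        assert np.isclose(s["c"] / s["a"], 2.0)
        assert np.isclose(np.exp(np.log(s).mean()), 1.0)  # geometric mean 1

    def test_hand_arithmetic(self):
        counts = pd.DataFrame({"s1": [2, 8, 6], "s2": [4, 16, 12],
                               "s3": [2, 8, 6], "s4": [16, 64, 48]})
        # per-gene geometric means: 4, 16, 12; every gene gives the same
        # per-sample ratios (0.5, 1, 0.5, 4), whose geometric mean is already 1
        s = expression.size_factors(counts)
        assert np.allclose(s.to_numpy(), [0.5, 1.0, 0.5, 4.0])

    def test_no_common_gene_raises(self):
        counts = pd.DataFrame({"a": [1, 0], "b": [0, 1]})
        with pytest.raises(ValueError):
            expression.size_factors(counts)


class TestRegularizedLog:
    def test_trivial_values(self):
        counts = pd.DataFrame({"s": [0, 15]}, index=["g0", "g15"])
        s = pd.Series([1.0], index=["s"])
        T = expression.regularized_log(counts, s)
        assert T.loc["g0", "s"] == 0.0       # log2(0 + 1)
        assert T.loc["g15", "s"] == 4.0      # log2(15 + 1)

    def test_nonpositive_size_factor_raises(self):
        counts = pd.DataFrame({"s": [1]})
        with pytest.raises(ValueError):
            expression.regularized_log(counts, pd.Series([0.0], index=["s"]))

    def test_variance_stabilizes_at_high_mean(self, rng):
        # per-gene SD of the transform should not keep growing with the mean
        means = np.array([5, 50, 500, 5000], dtype=float)
        counts = pd.DataFrame(
            np.stack([rng.negative_binomial(10, 10 / (10 + m), 200) for m in means]),
            columns=[f"s{i}" for i in range(200)])
        s = pd.Series(1.0, index=counts.columns)
        T = expression.regularized_log(counts, s)
        sds = T.std(axis=1).to_numpy()
        assert sds[3] < sds[0] * 3  # far from the sqrt-scale blowup of raw counts


class TestNBDifferentialExpression:
    def test_poisson_limit_matches_statsmodels(self):
        counts, design, _ = simulate.gen_counts(
            n_genes=20, genets=("A", "B", "C"), dispersion=0.01, seed=42)
        res = expression.fit_nb_de(counts, design, dispersion=1e-8)
        X, names = expression.design_matrix(design.loc[counts.columns])
        s = expression.size_factors(counts)
        offset = np.log(s.to_numpy())
        for gene in counts.index:
            y = counts.loc[gene].to_numpy()
            glm = sm.GLM(y, X, family=sm.families.Poisson(), offset=offset).fit()
            beta = glm.params[names.index("state_symbiotic")]
            se = glm.bse[names.index("state_symbiotic")]
            assert np.isclose(res.loc[gene, "log2FoldChange"], beta / np.log(2),
                              atol=1e-4)
            p_ref = 2 * stats.norm.sf(abs(beta / se))
            assert abs(res.loc[gene, "pvalue"] - p_ref) < 1e-4

    def test_null_calibration(self):
        counts, design, _ = simulate.gen_counts(
            n_genes=1000, frac_de=0.0, dispersion=0.1, seed=40)
        res = expression.fit_nb_de(expression.filter_low_counts(counts), design)
        rate = (res["pvalue"] < 0.05).mean()
        assert 0.02 <= rate <= 0.08  # acceptance tests the tighter band

    def test_planted_lfc_recovery(self, paired_counts):
        counts, design, truth = paired_counts
        res = expression.fit_nb_de(expression.filter_low_counts(counts), design)
        planted = [g for g in truth.planted["de_genes"] if g in res.index]
        signed = (res.loc[planted, "log2FoldChange"]
                  * np.sign(truth.planted["true_lfc"].loc[planted]))
        assert abs(signed.mean() - 2.0) < 0.35

    def test_discoveries_enriched_for_planted(self):
        counts, design, truth = simulate.gen_counts(
            n_genes=1000, frac_de=0.02, lfc=2.0, dispersion=0.1, seed=17)
        res = expression.fit_nb_de(expression.filter_low_counts(counts), design)
        called = set(res.index[res["significant"]])
        planted = set(truth.planted["de_genes"]) & set(res.index)
        assert called, "no discoveries at FDR < 0.1 despite planted effects"
        precision = len(called & planted) / len(called)
        base_rate = len(planted) / len(res)
        assert precision >= 10 * base_rate

    def test_invariant_to_row_and_column_order(self, paired_counts, rng):
        counts, design, _ = paired_counts
        counts = expression.filter_low_counts(counts)
        res1 = expression.fit_nb_de(counts, design)
        shuffled = counts.sample(frac=1.0, random_state=1)
        shuffled = shuffled[list(rng.permutation(counts.columns))]
        res2 = expression.fit_nb_de(shuffled, design)
        pd.testing.assert_series_equal(
            res1["log2FoldChange"].sort_index(),
            res2["log2FoldChange"].sort_index(), rtol=1e-6)

    def test_sign_convention_positive_in_symbiotic(self):
        # one gene forced much higher in symbiotic samples
        counts, design, _ = simulate.gen_counts(n_genes=50, seed=9)
        counts.iloc[0] = np.where(design["state"] == "symbiotic", 400, 50)
        res = expression.fit_nb_de(counts, design)
        assert res["log2FoldChange"].iloc[0] > 1.5

    def test_bh_against_independent_implementation(self, rng):
        for _ in range(5):
            p = rng.uniform(0, 1, 100)
            from statsmodels.stats.multitest import multipletests
            assert np.allclose(multipletests(p, method="fdr_bh")[1],
                               reference_bh(p))

    def test_bh_discoveries_monotone_in_level(self, paired_counts):
        counts, design, _ = paired_counts
        res = expression.fit_nb_de(expression.filter_low_counts(counts), design)
        padj = res["padj"].dropna()
        n_disc = [int((padj < q).sum()) for q in (0.01, 0.05, 0.1, 0.2)]
        assert n_disc == sorted(n_disc)


class TestPca:
    def test_identical_samples_zero_variance(self):
        T = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]})
        scores, frac = expression.pca(T)
        assert np.allclose(scores.to_numpy(), 0)

    def test_two_gene_analytic_direction(self):
        # samples spread along the (1, 1)/sqrt(2) direction in gene space
        t = np.array([[1.0, 2.0, 3.0, 4.0], [1.1, 2.1, 3.1, 4.1]])
        T = pd.DataFrame(t, index=["g1", "g2"], columns=list("abcd"))
        M = T.to_numpy().T
        M = M - M.mean(axis=0)
        evals, evecs = np.linalg.eigh(M.T @ M)
        pc1 = evecs[:, -1]
        scores, frac = expression.pca(T)
        proj = M @ pc1
        assert np.allclose(np.abs(scores["PC1"].to_numpy()), np.abs(proj))
        assert frac[0] > 0.999

    def test_reconstruction_identity(self, rng):
        T = pd.DataFrame(rng.normal(size=(30, 6)), columns=[f"s{i}" for i in range(6)])
        M = T.to_numpy().T
        Mc = M - M.mean(axis=0)
        U, S, Vt = np.linalg.svd(Mc, full_matrices=False)
        assert np.allclose(U @ np.diag(S) @ Vt, Mc, atol=1e-10)
        scores, frac = expression.pca(T)
        assert frac.sum() <= 1.0 + 1e-12

    def test_single_sample_raises(self):
        with pytest.raises(ValueError):
            expression.pca(pd.DataFrame({"a": [1.0, 2.0]}))


class TestPermanova:
    def _design(self, genets, states, ids=None):
        ids = ids or [f"s{i}" for i in range(len(genets))]
        return pd.DataFrame({"genet": genets, "state": states},
                            index=pd.Index(ids, name="sample_id"))

    def test_hand_computed_partition_single_factor(self):
        # 4 samples, 1 informative gene; one-way partition checked by hand
        T = pd.DataFrame({"s0": [0.0], "s1": [1.0], "s2": [10.0], "s3": [11.0]})
        design = self._design(["g1", "g1", "g2", "g2"],
                              ["symbiotic", "aposymbiotic"] * 2)
        res = expression.permanova(T, design, factors=("genet",), n_perm=99, seed=0)
        # total SS = sum of squared deviations from the mean (Euclidean, 1-D)
        vals = np.array([0.0, 1.0, 10.0, 11.0])
        ss_total = ((vals - vals.mean()) ** 2).sum()
        ss_within = sum(((vals[i:i + 2] - vals[i:i + 2].mean()) ** 2).sum()
                        for i in (0, 2))
        ss_between = ss_total - ss_within
        f_expected = (ss_between / 1) / (ss_within / 2)
        assert np.isclose(res.table.loc["genet", "SS"], ss_between)
        assert np.isclose(res.table.loc["genet", "F"], f_expected)
        assert np.isclose(res.table["R2"].drop("total").sum(), 1.0)

    def test_strong_separation_near_minimum_p(self):
        # a huge state offset: only permutations reproducing the exact
        # symbiotic/aposymbiotic split can match the observed F, so p sits
        # at (or within a few exceedances of) the attainable minimum
        counts, design, _ = simulate.gen_counts(
            n_genes=40, genets=tuple("ABCDEF"), seed=3)
        T = expression.regularized_log(counts, expression.size_factors(counts))
        T.loc[:, design.index[design["state"] == "symbiotic"]] += 50.0
        res = expression.permanova(T, design, factors=("state",), n_perm=199, seed=1)
        assert res.table.loc["state", "p"] <= 4 / 200

    def test_sequential_r2_sums_to_one(self):
        counts, design, _ = simulate.gen_counts(n_genes=50, seed=4)
        T = expression.regularized_log(counts, expression.size_factors(counts))
        res = expression.permanova(T, design, n_perm=49, seed=2)
        assert np.isclose(res.table["R2"].drop("total").sum(), 1.0)

    def test_confounded_factor_raises(self):
        T = pd.DataFrame(np.random.default_rng(0).normal(size=(5, 4)),
                         columns=[f"s{i}" for i in range(4)])
        design = self._design(["g1", "g1", "g2", "g2"],
                              ["symbiotic", "symbiotic", "aposymbiotic", "aposymbiotic"])
        with pytest.raises(ValueError, match="confounded"):
            expression.permanova(T, design, factors=("genet", "state"), n_perm=9, seed=0)

    def test_seed_reproducible_and_converging(self):
        counts, design, _ = simulate.gen_counts(n_genes=50, seed=5)
        T = expression.regularized_log(counts, expression.size_factors(counts))
        p1 = expression.permanova(T, design, n_perm=999, seed=7).table["p"]
        p2 = expression.permanova(T, design, n_perm=999, seed=7).table["p"]
        pd.testing.assert_series_equal(p1, p2)
        p3 = expression.permanova(T, design, n_perm=999, seed=8).table["p"]
        mc_se = np.sqrt(0.25 / 999)
        assert (np.abs(p1.dropna() - p3.dropna()) <= 4 * mc_se).all()


class TestPairedTTest:
    def test_equal_vectors(self):
        with pytest.raises(ValueError):
            expression.paired_onetailed_ttest([1, 2, 3], [1, 2, 3])

    def test_half_p_when_no_shift(self):
        # antisymmetric differences with nonzero variance, mean zero -> p = 0.5
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([2.0, 1.0, 4.0, 3.0])
        t, df, p = expression.paired_onetailed_ttest(x, y)
        assert t == 0.0 and p == 0.5 and df == 3

    def test_textbook_formula(self):
        d = np.array([1.0, 2.0, 3.0, 0.0, 1.0, 2.0])
        t, df, p = expression.paired_onetailed_ttest(d, np.zeros(6))
        t_ref = d.mean() / (d.std(ddof=1) / np.sqrt(6))
        assert np.isclose(t, t_ref) and df == 5
        assert np.isclose(p, stats.t.sf(t_ref, 5))
        # scipy cross-check
        res = stats.ttest_rel(d, np.zeros(6), alternative="greater")
        assert np.isclose(p, res.pvalue)

    def test_larger_mean_shift_increases_t(self):
        # adding a constant to the differences raises the mean at fixed sd
        x = np.array([1.0, 2.0, 3.0, 0.5])
        t1, _, p1 = expression.paired_onetailed_ttest(x, np.zeros(4))
        t2, _, p2 = expression.paired_onetailed_ttest(x + 1.0, np.zeros(4))
        assert t2 > t1 and p2 < p1
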