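import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps

from oracles import hypergeom_upper_tail, ols_normal_equations, poisson_irls
from polyfoot.covariation import (
    bc_bootstrap_ci,
    bin_surface,
    class_compare,
    cohens_f2,
    correlate,
    fit_dxy_model,
    fit_fst_model,
    fixation_glm,
    hypergeom_enrichment,
    ols_fit,
    pc1_regression,
    repeatability,
    select_imbalance,
    sexbias_bins,
)


def _pair_table(rng, n=200, beta=None, sigma=0.5):
    """Synthetic pair table with a known generating model for fst_logit."""
    d1 = rng.normal(0, 1, n)
    d2 = rng.normal(0, 1, n)
    beta = beta or {}
    y = (
        beta.get("const", -1.0)
        + beta.get("D1", 0.0) * d1
        + beta.get("D2", 0.0) * d2
        + beta.get("D1_sq", 0.0) * d1**2
        + beta.get("D2_sq", 0.0) * d2**2
        + beta.get("D1xD2", 0.0) * d1 * d2
        + rng.normal(0, sigma, n)
    )
    return pd.DataFrame(
        {
            "gene_id": [f"g{i}" for i in range(n)],
            "pair": "0-1",
            "D1": d1,
            "D2": d2,
            "fst_logit": y,
            "dxy_log10": y,
            "fst": 1 / (1 + np.exp(-y)),
        }
    )


class TestDivergenceModels:
    def test_noise_free_coefficients_recovered_exactly(self, rng):
        beta = {"const": -1.2, "D1": 0.3, "D2": 0.1, "D1_sq": 0.05,
                "D2_sq": -0.04, "D1xD2": -0.55}
        t = _pair_table(rng, n=100, beta=beta, sigma=0.0)
        fit = fit_fst_model(t, model=1)
        for term, value in beta.items():
            assert fit.beta(term) == pytest.approx(value, abs=1e-8)
        assert fit.r2 == pytest.approx(1.0)

    def test_matches_normal_equations_oracle(self, rng):
        t = _pair_table(rng, n=50, beta={"D1xD2": -0.5}, sigma=0.7)
        fit = fit_fst_model(t, model=1)
        x = np.column_stack(
            [np.ones(50), t.D1, t.D2, t.D1**2, t.D2**2, t.D1 * t.D2]
        )
        beta, se, tval, r2 = ols_normal_equations(x, t.fst_logit.to_numpy())
        np.testing.assert_allclose(fit.table["beta"], beta, atol=1e-10)
        np.testing.assert_allclose(fit.table["se"], se, atol=1e-10)
        assert fit.r2 == pytest.approx(r2, abs=1e-10)

    def test_interaction_recovered_within_3_se_under_noise(self, rng):
        """R2 around 0.1, n = 10^4: the design of the divergence models."""
        t = _pair_table(rng, n=10_000, beta={"D1xD2": -0.55}, sigma=1.6)
        fit = fit_fst_model(t, model=1)
        assert 0.05 < fit.r2 < 0.2
        assert abs(fit.beta("D1xD2") - (-0.55)) < 3 * fit.se("D1xD2")

    def test_quadratic_only_model_leaves_interaction_null(self, rng):
        """Pure quadratic generation: the interaction stays non-significant."""
        hits = 0
        for rep in range(50):
            t = _pair_table(
                rng, n=400,
                beta={"D1_sq": -0.03, "D2_sq": -0.04}, sigma=0.1,
            )
            fit = fit_dxy_model(t, model=1)
            if fit.pvalue("D1xD2") < 0.05:
                hits += 1
        assert hits <= 10  # ~5% type-I rate; allow 20% at 50 reps

    def test_rank_deficient_design_names_the_term(self, rng):
        t = _pair_table(rng, n=50)
        t["gc_content"] = 0.5  # constant column
        t["length"] = 1000
        t["ratio1"] = t["D1"]
        t["ratio2"] = t["D2"]
        with pytest.raises(ValueError, match="collinear"):
            fit_fst_model(t, model=2)

    def test_listwise_deletion(self, rng):
        t = _pair_table(rng, n=60)
        t.loc[:9, "D1"] = np.nan
        fit = fit_fst_model(t, model=1)
        assert fit.n == 50


class TestCohensF2:
    def test_closed_forms(self, rng):
        t = _pair_table(rng, n=100, beta={"D1xD2": -0.4}, sigma=0.5)
        full = fit_fst_model(t, model=1)
        assert cohens_f2(full, full) == pytest.approx(0.0)

        class Dummy:
            pass

        f, r = Dummy(), Dummy()
        f.r2, f.response, f.terms = 0.2, "y", ["a", "b"]
        r.r2, r.response, r.terms = 0.1, "y", ["a"]
        assert cohens_f2(f, r) == pytest.approx(0.125)

    def test_against_direct_refit(self, rng):
        t = _pair_table(rng, n=100, beta={"D1xD2": -0.5, "D1": 0.2}, sigma=0.4)
        t["D1_sq"] = t.D1**2
        t["D2_sq"] = t.D2**2
        t["D1xD2"] = t.D1 * t.D2
        full = ols_fit(t, "fst_logit", ["D1", "D2", "D1_sq", "D2_sq", "D1xD2"])
        red = ols_fit(t, "fst_logit", ["D1", "D2", "D1_sq", "D2_sq"])
        expected = (full.r2 - red.r2) / (1 - full.r2)
        assert cohens_f2(full, red) == pytest.approx(expected, abs=1e-12)


class TestRepeatability:
    def test_identical_vectors_give_perfect_repeatability(self, rng):
        v = rng.normal(0, 1, 200)
        res = repeatability(pd.DataFrame({"a": v, "b": v, "c": v}))
        assert res.icc_R == pytest.approx(1.0)
        assert res.pc1_variance_fraction == pytest.approx(1.0)
        assert res.variance_fractions.sum() == pytest.approx(1.0)

    def test_independent_noise_gives_near_zero_icc(self, rng):
        x = rng.normal(0, 1, (10_000, 3))
        res = repeatability(pd.DataFrame(x, columns=list("abc")))
        assert abs(res.icc_R) < 0.03

    def test_five_gene_worked_anova(self):
        """Hand-computed one-way ANOVA: MS_B, MS_W and R must match exactly."""
        x = np.array(
            [[1.0, 2.0, 3.0],
             [4.0, 4.0, 4.0],
             [0.0, 1.0, 2.0],
             [5.0, 6.0, 4.0],
             [2.0, 2.0, 5.0]]
        )
        # gene means: 2, 4, 1, 5, 3; grand mean 3
        # SS_between = 3 * (1+1+4+4+0) = 30 -> MS_B = 30/4 = 7.5
        # SS_within = (1+0+1)+(0)+(1+0+1)+(0+1+1)+(1+1+4) = 12 -> MS_W = 12/10 = 1.2
        res = repeatability(pd.DataFrame(x, columns=list("abc")))
        assert res.ms_between == pytest.approx(7.5)
        assert res.ms_within == pytest.approx(1.2)
        assert res.icc_R == pytest.approx((7.5 - 1.2) / (7.5 + 2 * 1.2))

    def test_too_few_genes_is_an_error(self):
        with pytest.raises(ValueError):
            repeatability(pd.DataFrame({"a": [1.0], "b": [2.0], "c": [3.0]}))


class TestPc1Regression:
    def test_standardized_betas_match_oracle(self, rng):
        n = 300
        length = rng.normal(1000, 300, n)
        gc = rng.normal(0.4, 0.05, n)
        pc1 = 0.3 * (length - 1000) / 300 + rng.normal(0, 1, n)
        fit = pc1_regression(pc1, pd.DataFrame({"length": length, "gc": gc}))
        zl = (length - length.mean()) / length.std()
        zg = (gc - gc.mean()) / gc.std()
        zy = (pc1 - pc1.mean()) / pc1.std()
        x = np.column_stack([np.ones(n), zl, zg])
        beta, *_ = ols_normal_equations(x, zy)
        assert fit.beta("length") == pytest.approx(beta[1], abs=1e-9)
        assert fit.beta("gc") == pytest.approx(beta[2], abs=1e-9)


class TestBinSurface:
    def test_equal_marginal_counts(self, rng):
        d1, d2 = rng.normal(size=801), rng.normal(size=801)
        surf = bin_surface(d1, d2, rng.normal(size=801))
        assert surf.marginal1.min() >= 801 // 8
        assert surf.marginal1.max() <= 801 // 8 + 1
        assert surf.counts.sum() == 801

    def test_saddle_statistic_peaks_in_opposite_sign_corners(self, rng):
        d1, d2 = rng.normal(size=2000), rng.normal(size=2000)
        surf = bin_surface(d1, d2, -d1 * d2)
        corners = surf.mean[[0, 0, 7, 7], [0, 7, 0, 7]]
        assert corners[1] == surf.mean.max() or corners[2] == surf.mean.max()
        assert max(corners[1], corners[2]) > max(corners[0], corners[3])

    def test_cell_means_match_brute_force_group_by(self, rng):
        d1, d2 = rng.normal(size=640), rng.normal(size=640)
        stat = rng.normal(size=640)
        surf = bin_surface(d1, d2, stat)
        # recompute one cell by brute force from the returned assignment logic
        order1 = np.argsort(d1, kind="stable")
        r1 = np.empty_like(order1)
        r1[order1] = np.arange(640)
        b1 = r1 * 8 // 640
        order2 = np.argsort(d2, kind="stable")
        r2 = np.empty_like(order2)
        r2[order2] = np.arange(640)
        b2 = r2 * 8 // 640
        for i, j in [(0, 0), (3, 5), (7, 7)]:
            sel = (b1 == i) & (b2 == j)
            if sel.any():
                assert surf.mean[i, j] == pytest.approx(stat[sel].mean())

    def test_too_few_genes_is_an_error(self, rng):
        with pytest.raises(ValueError):
            bin_surface(rng.normal(size=30), rng.normal(size=30), rng.normal(size=30))


class TestSelectImbalance:
    def _table(self, rows):
        df = pd.DataFrame(rows, columns=["gene_id", "D1", "D2", "fst"])
        df["pair"] = "0-1"
        return df

    def test_strict_thresholds(self):
        t = self._table(
            [("in", 1.5, -1.5, 0.35),      # |diff| = 3.0 > 2.5, fst > 0.3
             ("edge_fst", 1.5, -1.5, 0.30),  # fst not strictly > 0.3
             ("edge_d", 1.25, -1.25, 0.5),   # |diff| = 2.5 not > 2.5
             ("out", 0.5, 0.2, 0.9)]
        )
        res = select_imbalance(t)
        assert res.genes == ("in",)

    def test_empty_table(self):
        res = select_imbalance(self._table([]))
        assert res.genes == ()

    def test_raw_scale_switch(self):
        t = self._table([("a", 0.1, -0.1, 0.9)])
        t["D1_raw"], t["D2_raw"] = 3.0, -3.0
        assert select_imbalance(t, use_std=False).genes == ("a",)
        assert select_imbalance(t, use_std=True).genes == ()


class TestEnrichment:
    def test_set_equal_to_universe_is_never_enriched(self):
        universe = {f"g{i}" for i in range(20)}
        tm = {"T1": {f"g{i}" for i in range(5)}}
        assert hypergeom_enrichment(universe, universe, tm).empty

    def test_complete_overlap_exact_value(self):
        universe = {f"g{i}" for i in range(20)}
        term = {f"g{i}" for i in range(5)}
        res = hypergeom_enrichment(term, universe, {"T": term})
        from math import comb

        assert res.iloc[0]["p"] == pytest.approx(1 / comb(20, 5), rel=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exact_enumeration_for_small_universes(self, seed):
        rng = np.random.default_rng(seed)
        n_univ = int(rng.integers(10, 31))
        universe = {f"g{i}" for i in range(n_univ)}
        term = set(rng.choice(sorted(universe), rng.integers(2, n_univ // 2), replace=False))
        gene_set = set(rng.choice(sorted(universe), rng.integers(2, n_univ // 2), replace=False))
        res = hypergeom_enrichment(gene_set, universe, {"T": term},
                                   p_cut=1.1, min_genes=0)
        k = len(gene_set & term)
        expected = hypergeom_upper_tail(n_univ, len(term), len(gene_set), k)
        assert res.iloc[0]["p"] == pytest.approx(expected, rel=1e-10)

    def test_set_outside_universe_is_an_error(self):
        with pytest.raises(ValueError):
            hypergeom_enrichment({"x"}, {"a", "b"}, {})


class TestClassCompare:
    def test_shifted_classes_detected_with_high_power(self, rng):
        res = class_compare(
            rng.normal(1.0, 1.0, 100), rng.normal(0.0, 1.0, 100),
            label="shifted", seed=1,
        )
        assert res.p < 1e-6
        assert res.ci_in[0] <= res.mean_in <= res.ci_in[1]

    def test_welch_matches_scipy(self, rng):
        a, b = rng.normal(0, 1, 40), rng.normal(0.2, 2, 150)
        res = class_compare(a, b, seed=0)
        t, p = sps.ttest_ind(a, b, equal_var=False)
        assert res.t == pytest.approx(t)
        assert res.p == pytest.approx(p)

    def test_constant_vector_bootstrap_is_zero_width(self):
        lo, hi = bc_bootstrap_ci(np.full(30, 2.5), B=100, seed=0)
        assert lo == hi == 2.5

    def test_tiny_class_is_an_error(self, rng):
        with pytest.raises(ValueError):
            class_compare(np.ones(3), rng.normal(size=50))


class TestSexBiasBins:
    def _inputs(self, rng, n=800, effect=0.0):
        genes = [f"g{i}" for i in range(n)]
        lfc = np.concatenate([rng.uniform(0.5, 5, n // 2), rng.uniform(-5, -0.5, n - n // 2)])
        bias = np.where(lfc > 0, "FBG", "MBG")
        expr = pd.DataFrame(
            {"gene_id": genes, "fpkm": rng.lognormal(2, 1, n),
             "log2fc_sex": lfc, "bias_class": bias}
        )
        gt = pd.DataFrame({"gene_id": genes})
        gt["fst_logit"] = rng.normal(0, 1, n) + effect * np.abs(lfc)
        return expr, gt

    def test_bins_are_eight_quartile_groups(self, rng):
        expr, gt = self._inputs(rng)
        res = sexbias_bins(expr, gt, "fst_logit", n_perm=99, seed=0)
        assert len(res.bins) == 8
        assert set(res.bins["bias_class"]) == {"FBG", "MBG"}
        assert res.bins["n"].sum() == len(gt)
        assert res.bins["n"].max() - res.bins["n"].min() <= 1

    def test_strong_effect_saturates_the_permutation_p(self, rng):
        expr, gt = self._inputs(rng, effect=1.0)
        res = sexbias_bins(expr, gt, "fst_logit", n_perm=199, seed=0)
        assert res.p_perm == pytest.approx(1 / 200)

    def test_agrees_with_anova_p_for_normal_data(self, rng):
        expr, gt = self._inputs(rng, n=3000, effect=0.02)
        res = sexbias_bins(expr, gt, "fst_logit", n_perm=2000, seed=0)
        merged = expr.merge(gt, on="gene_id")
        # reproduce the binning to get the parametric reference
        groups = []
        for cls in ("FBG", "MBG"):
            sub = merged[merged["bias_class"] == cls].sort_values("log2fc_sex", kind="stable")
            for q in np.array_split(sub["fst_logit"].to_numpy(), 4):
                groups.append(q)
        f, p = sps.f_oneway(*groups)
        assert res.p_perm == pytest.approx(p, abs=0.02)


class TestFixationGlm:
    def _table(self, rng, n=2000, beta_class=0.0):
        fpkm = rng.lognormal(2, 1.2, n)
        is_focal = rng.random(n) < 0.3
        eta = 0.3 + 0.1 * (np.log(fpkm) - np.log(fpkm).mean()) + beta_class * is_focal
        y = np.clip(rng.poisson(np.exp(eta)), 0, 3)
        return pd.DataFrame(
            {"gene_id": [f"g{i}" for i in range(n)], "n_pops_poly": y,
             "fpkm": fpkm, "is_focal": is_focal}
        )

    def test_quadratic_fit_matches_irls_oracle(self, rng):
        t = self._table(rng)
        fit = fixation_glm(t, form="quadratic")
        x1 = np.log(t["fpkm"].to_numpy())
        x1 = x1 - x1.mean()
        cls = t["is_focal"].to_numpy().astype(float)
        x = np.column_stack([np.ones(len(t)), x1, x1**2, cls, cls * x1**2])
        beta, _ = poisson_irls(x, t["n_pops_poly"].to_numpy().astype(float))
        np.testing.assert_allclose(fit.coefficients["beta"], beta, atol=1e-8)

    def test_class_effect_recovered(self, rng):
        t = self._table(rng, n=5000, beta_class=0.4)
        fit = fixation_glm(t, form="binned9")
        row = fit.tests.set_index("term").loc["class"]
        assert row["p"] < 0.01

    def test_null_class_p_is_calibrated(self, rng):
        pvals = []
        for _ in range(60):
            t = self._table(rng, n=400, beta_class=0.0)
            fit = fixation_glm(t, form="binned9")
            pvals.append(fit.tests.set_index("term").loc["class", "p"])
        # under the null the LLR p-values should be roughly uniform
        assert sps.kstest(pvals, "uniform").pvalue > 0.01

    def test_degenerate_response_is_an_error(self, rng):
        t = self._table(rng, n=50)
        t["n_pops_poly"] = 2
        with pytest.raises(ValueError, match="degenerate"):
            fixation_glm(t)

    def test_out_of_range_response_is_an_error(self, rng):
        t = self._table(rng, n=50)
        t.loc[0, "n_pops_poly"] = 4
        with pytest.raises(ValueError, match="0..3"):
            fixation_glm(t)


class TestCorrelate:
    def test_identities(self, rng):
        a = rng.normal(size=20)
        assert correlate(a, a) == pytest.approx(1.0)
        assert correlate(a, -a) == pytest.approx(-1.0)

    def test_matches_covariance_formula(self, rng):
        a, b = rng.normal(size=20), rng.normal(size=20)
        expected = np.cov(a, b)[0, 1] / (a.std(ddof=1) * b.std(ddof=1))
        assert correlate(a, b) == pytest.approx(expected, abs=1e-12)

    def test_pairwise_complete_and_degenerate(self, rng):
        a = np.array([1.0, np.nan, 2.0, 3.0])
        b = np.array([2.0, 5.0, 4.0, 6.0])
        assert correlate(a, b) == pytest.approx(1.0)
        assert np.isnan(correlate(np.ones(5), rng.normal(size=5)))
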