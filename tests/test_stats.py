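"""Permutation inference: enumeration oracles, calibration, adjustment."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from nftrial.cohort import simulate_covariate_null
from nftrial.stats import (PermAncovaResult, change_scores, fdr_adjust,
                           perm_ancova, perm_anova_baseline, perm_regression,
                           pool_over_imputations, posthoc_pairwise)


class TestChangeScores:
    def test_identical_tables_give_zeros(self, rng):
        pre = pd.DataFrame(rng.normal(size=(5, 3)), columns=list("abc"))
        assert (change_scores(pre, pre.copy()) == 0).all().all()

    def test_matches_elementwise_subtraction(self, rng):
        pre = pd.DataFrame(rng.normal(size=(6, 4)), columns=list("abcd"))
        post = pd.DataFrame(rng.normal(size=(6, 4)), columns=list("abcd"))
        out = change_scores(pre, post)
        assert np.allclose(out.to_numpy(), post.to_numpy() - pre.to_numpy())
        assert change_scores(pd.DataFrame({"a": [15.70]}),
                             pd.DataFrame({"a": [18.15]})).iloc[0, 0] \
            == pytest.approx(2.45)

    def test_id_mismatch_errors(self):
        pre = pd.DataFrame({"a": [1.0]}, index=["x"])
        post = pd.DataFrame({"a": [1.0]}, index=["y"])
        with pytest.raises(ValueError, match="ids"):
            change_scores(pre, post)


class TestPermAnova:
    def test_identical_values_give_f_zero_p_one(self):
        values = np.full(9, 2.0)
        groups = np.repeat(["a", "b", "c"], 3)
        F, p = perm_anova_baseline(values, groups, n_perm=99, seed=0)
        assert F == 0.0 and p == 1.0

    def test_monte_carlo_agrees_with_exhaustive_enumeration(self):
        """n = 6, two per group: compare against the exact p over all
        90 distinct label assignments."""
        values = np.array([1.2, 0.8, 2.9, 3.4, 0.1, 1.7])
        groups = np.array(["a", "a", "b", "b", "c", "c"])

        def f_stat(y):
            grand = y.mean()
            ss_b = sum(2 * (y[groups == g].mean() - grand) ** 2
                       for g in "abc")
            ss_w = sum(((y[groups == g] - y[groups == g].mean()) ** 2).sum()
                       for g in "abc")
            return (ss_b / 2) / (ss_w / 3)

        obs = f_stat(values)
        exact_ge = sum(f_stat(np.array(perm)) >= obs - 1e-12
                       for perm in itertools.permutations(values))
        p_exact = exact_ge / math.factorial(6)
        n_perm = 4000
        _, p_mc = perm_anova_baseline(values, groups, n_perm=n_perm, seed=1)
        se = math.sqrt(p_exact * (1 - p_exact) / n_perm)
        assert abs(p_mc - p_exact) < 2 * se + 1 / (n_perm + 1)

    def test_huge_separation_gives_minimal_p(self, rng):
        values = np.concatenate([rng.normal(0, 1, 5), rng.normal(50, 1, 5),
                                 rng.normal(100, 1, 5)])
        groups = np.repeat(["a", "b", "c"], 5)
        _, p = perm_anova_baseline(values, groups, n_perm=199, seed=2)
        assert p == pytest.approx(1 / 200)

    def test_invalid_inputs_error(self):
        with pytest.raises(ValueError):
            perm_anova_baseline(np.ones(4), np.repeat(["a", "b"], 2),
                                n_perm=0)
        with pytest.raises(ValueError, match="2 groups"):
            perm_anova_baseline(np.ones(4), np.repeat(["a"], 4), n_perm=10)


class TestPermAncova:
    def _toy(self, seed=3, n=60, effect=0.0):
        df = simulate_covariate_null(n, seed=seed)
        df.loc[df["group"] == "CT-NF", "change"] += effect
        return df

    def test_f_matches_statsmodels_anova(self):
        """The observed F (group added to covariates) equals the
        partial F test from statsmodels OLS."""
        df = self._toy(seed=4, effect=1.0)
        cov = df[["pre", "age", "sex"]]
        res = perm_ancova(df["change"].to_numpy(), df["group"].to_numpy(),
                          cov, n_perm=10, seed=0)
        X_red = sm.add_constant(cov.to_numpy())
        dummies = pd.get_dummies(df["group"], drop_first=True).to_numpy(float)
        X_full = np.column_stack([X_red, dummies])
        fit_full = sm.OLS(df["change"], X_full).fit()
        fit_red = sm.OLS(df["change"], X_red).fit()
        f_sm = fit_full.compare_f_test(fit_red)[0]
        assert res.F == pytest.approx(f_sm, rel=1e-8)
        assert res.df1 == 2 and res.df2 == len(df) - 6

    def test_orthogonal_covariates_reduce_to_one_way_anova(self, rng):
        """Covariates orthogonal to both the group dummies and the outcome
        leave the group and residual sums of squares unchanged."""
        n = 12
        groups = np.repeat(["a", "b", "c"], 4)
        y = rng.normal(size=n)
        D = np.column_stack([np.ones(n)]
                            + [(groups == g).astype(float)
                               for g in ("b", "c")] + [y])
        raw = rng.normal(size=(n, 2))
        ortho, _ = np.linalg.qr(np.column_stack([D, raw]))
        cov = pd.DataFrame(ortho[:, 4:6], columns=["c1", "c2"])
        res = perm_ancova(y, groups, cov, n_perm=10, seed=0)
        grand = y.mean()
        ss_b = sum(4 * (y[groups == g].mean() - grand) ** 2 for g in "abc")
        ss_w = sum(((y[groups == g] - y[groups == g].mean()) ** 2).sum()
                   for g in "abc")
        f_anova_matched_df = (ss_b / 2) / (ss_w / res.df2)
        assert res.F == pytest.approx(f_anova_matched_df, rel=1e-8)

    def test_monte_carlo_agrees_with_exhaustive_residual_permutations(self):
        """n = 7 toy: every one of the 7! Freedman-Lane residual
        permutations is enumerated and compared with the Monte-Carlo p."""
        rng = np.random.default_rng(5)
        n = 7
        groups = np.array(["a", "a", "a", "b", "b", "c", "c"])
        cov = pd.DataFrame({"x": rng.normal(size=n)})
        y = rng.normal(size=n) + 0.8 * (groups == "a")

        X_full = np.column_stack([np.ones(n),
                                  (groups == "b").astype(float),
                                  (groups == "c").astype(float),
                                  cov["x"]])
        X_red = np.column_stack([np.ones(n), cov["x"]])
        Qf, _ = np.linalg.qr(X_full)
        Qr, _ = np.linalg.qr(X_red)
        df1, df2 = 2, n - 4

        def f_of(yv):
            rf = yv @ yv - (Qf.T @ yv) @ (Qf.T @ yv)
            rr = yv @ yv - (Qr.T @ yv) @ (Qr.T @ yv)
            return ((rr - rf) / df1) / (rf / df2)

        yhat = Qr @ (Qr.T @ y)
        resid = y - yhat
        obs = f_of(y)
        stats = [f_of(yhat + resid[list(perm)])
                 for perm in itertools.permutations(range(n))]
        p_exact = np.mean([s >= obs - 1e-12 for s in stats])
        res = perm_ancova(y, groups, cov, n_perm=4000, seed=6)
        se = math.sqrt(p_exact * (1 - p_exact) / 4000)
        assert abs(res.p_perm - p_exact) < 2 * se + 1 / 4001
        assert res.F == pytest.approx(obs, rel=1e-10)

    def test_eta_squared_boundaries(self):
        groups = np.repeat(["a", "b", "c"], 4)
        cov = pd.DataFrame({"x": np.tile([0.1, -0.1], 6)})
        pure = np.repeat([1.0, 2.0, 3.0], 4)
        res = perm_ancova(pure, groups, cov, n_perm=20, seed=0)
        assert res.eta_sq == pytest.approx(1.0, abs=1e-9)

    def test_type_one_error_near_nominal(self):
        """Null generator with covariate effects only: rejection at the
        0.05 level stays near nominal (light version; the full 1000-trial
        calibration lives in the acceptance suite)."""
        rej = 0
        n_rep = 250
        for r in range(n_rep):
            df = simulate_covariate_null(45, seed=10_000 + r)
            res = perm_ancova(df["change"].to_numpy(),
                              df["group"].to_numpy(),
                              df[["pre", "age", "sex"]], n_perm=299,
                              seed=r)
            rej += res.p_perm <= 0.05
        assert 0.02 <= rej / n_rep <= 0.09

    def test_missing_values_rejected(self):
        df = self._toy()
        y = df["change"].to_numpy()
        y[0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            perm_ancova(y, df["group"].to_numpy(),
                        df[["pre", "age", "sex"]], n_perm=10)

    def test_rank_deficient_design_names_aliased_columns(self):
        df = self._toy()
        cov = df[["pre", "age", "sex"]].copy()
        cov["dup"] = cov["pre"]
        with pytest.raises(ValueError, match="dup"):
            perm_ancova(df["change"].to_numpy(), df["group"].to_numpy(),
                        cov, n_perm=10)


class TestPosthoc:
    def test_identical_arms_give_adjusted_one(self):
        groups = np.repeat(["a", "b", "c"], 4)
        cov = pd.DataFrame({"x": np.arange(12.0)})
        out = posthoc_pairwise(np.full(12, 1.0), groups, cov, n_perm=99,
                               seed=0)
        assert set(out.values()) == {1.0}

    def test_bonferroni_triples_and_caps_raw_p(self):
        df = simulate_covariate_null(30, seed=20)
        df.loc[df["group"] == "CT-NF", "change"] += 3.0
        cov = df[["pre", "age", "sex"]].reset_index(drop=True)
        groups = df["group"].to_numpy()
        out = posthoc_pairwise(df["change"].to_numpy(), groups, cov,
                               n_perm=199, seed=7)
        levels = sorted(set(groups))
        pairs = [(a, b) for i, a in enumerate(levels)
                 for b in levels[i + 1:]]
        for k, pair in enumerate(pairs):
            mask = np.isin(groups, pair)
            raw = perm_ancova(df["change"].to_numpy()[mask], groups[mask],
                              cov.loc[mask].reset_index(drop=True),
                              n_perm=199, seed=7 + k).p_perm
            assert out[pair] == pytest.approx(min(1.0, 3 * raw))


class TestPermRegression:
    def test_perfect_correlation(self, rng):
        x = rng.normal(size=25)
        res = perm_regression(x.copy(), x, None, n_perm=199, seed=0)
        assert res.beta_std == pytest.approx(1.0, abs=1e-9)
        assert res.p_perm == pytest.approx(1 / 200)

    def test_monte_carlo_agrees_with_exhaustive_enumeration(self):
        """n = 8, no covariates: all 8! permutations of the outcome give
        the exact two-sided permutation p."""
        rng = np.random.default_rng(9)
        x = rng.normal(size=8)
        y = 0.7 * x + rng.normal(size=8)
        xs = (x - x.mean()) / x.std(ddof=1)
        ys = (y - y.mean()) / y.std(ddof=1)

        def t_of(yv):
            X = np.column_stack([np.ones(8), xs])
            beta = np.linalg.lstsq(X, yv, rcond=None)[0]
            resid = yv - X @ beta
            s2 = resid @ resid / 6
            se = np.sqrt(s2 * np.linalg.inv(X.T @ X)[1, 1])
            return beta[1] / se

        obs = abs(t_of(ys))
        # Freedman-Lane with intercept-only reduced model permutes the
        # centered outcome, i.e. enumerates outcome permutations.
        stats = [abs(t_of(np.array(p))) for p in
                 itertools.permutations(ys)]
        p_exact = np.mean([s >= obs - 1e-12 for s in stats])
        res = perm_regression(y, x, None, n_perm=4000, seed=10)
        se = math.sqrt(p_exact * (1 - p_exact) / 4000)
        assert abs(res.p_perm - p_exact) < 2 * se + 1 / 4001

    def test_zero_variance_predictor_errors(self, rng):
        with pytest.raises(ValueError, match="zero-variance"):
            perm_regression(rng.normal(size=10), np.full(10, 2.0), None,
                            n_perm=10)

    def test_beta_bounded_without_covariates(self, rng):
        for s in range(5):
            r = np.random.default_rng(s)
            res = perm_regression(r.normal(size=15), r.normal(size=15),
                                  None, n_perm=20, seed=s)
            assert abs(res.beta_std) <= 1.0 + 1e-12


class TestPoolingAndFDR:
    def _result(self, p, F=1.0, eta=0.1):
        return PermAncovaResult("o", F, 2, 50, eta, p)

    def test_single_result_passes_through(self):
        res = pool_over_imputations([self._result(0.2)])
        assert res.p_perm == 0.2 and res.meta["m"] == 1

    def test_median_pooling(self):
        pooled = pool_over_imputations([self._result(0.01),
                                        self._result(0.02),
                                        self._result(0.90)])
        assert pooled.p_perm == 0.02
        assert pooled.meta["pooling"] == "median"

    def test_idempotent_for_identical_results(self):
        pooled = pool_over_imputations([self._result(0.3, 2.0, 0.2)] * 5)
        assert (pooled.p_perm, pooled.F, pooled.eta_sq) == (0.3, 2.0, 0.2)

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            pool_over_imputations([])

    def test_single_p_unchanged(self):
        assert fdr_adjust([0.037]) == [0.037]

    def test_hand_computed_benjamini_hochberg(self):
        assert fdr_adjust([0.01, 0.02, 0.03, 0.04]) \
            == pytest.approx([0.04, 0.04, 0.04, 0.04])
        # independent step-up computation for an uneven set
        raw = [0.005, 0.04, 0.03, 0.8]
        m = len(raw)
        order = np.argsort(raw)
        adj = np.empty(m)
        running = 1.0
        for rank in range(m - 1, -1, -1):
            i = order[rank]
            running = min(running, raw[i] * m / (rank + 1))
            adj[i] = running
        assert fdr_adjust(raw) == pytest.approx(list(adj))

    def test_adjusted_at_least_raw_and_monotone(self, rng):
        raw = rng.uniform(0.001, 1.0, 20)
        adj = np.array(fdr_adjust(list(raw)))
        assert (adj >= raw - 1e-12).all()
        order = np.argsort(raw)
        assert (np.diff(adj[order]) >= -1e-12).all()

    def test_out_of_range_p_errors(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.0, 0.5])
        with pytest.raises(ValueError):
            fdr_adjust([1.5])
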