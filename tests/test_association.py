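"""Subject-level association statistics against textbook and library oracles."""

import numpy as np
import pytest

from statecue.association import (condition_fo_compare, group_compare,
                                  mediation_bca, partial_correlation,
                                  state_expression)

pingouin = pytest.importorskip("pingouin")


class TestStateExpression:
    def test_perfect_tracking(self, rng):
        t = rng.normal(size=40)
        assert state_expression([2.0 * t + 1.0], [t]) == pytest.approx(1.0)

    def test_decoupled_near_zero(self, rng):
        rs = [abs(state_expression([rng.normal(size=400)],
                                   [rng.normal(size=400)]))
              for _ in range(5)]
        assert np.mean(rs) < 0.15

    def test_concatenates_runs(self, rng):
        t1, t2 = rng.normal(size=20), rng.normal(size=25)
        r = state_expression([t1, t2], [t1, t2])
        assert r == pytest.approx(1.0)

    def test_gain_recovery(self, rng):
        """Subjects whose FO tracks the target with individual gain: the
        expression score should correlate with the planted gain."""
        n, W, noise = 50, 80, 0.3
        target = rng.normal(size=W)
        gains = rng.uniform(0.0, 1.0, n)
        expr = np.array([
            state_expression([g * target + rng.normal(0, noise, W)], [target])
            for g in gains])
        assert np.corrcoef(expr, gains)[0, 1] >= 0.5

    def test_constant_fo_nan(self):
        assert np.isnan(state_expression([np.ones(20)],
                                         [np.arange(20.0)]))

    def test_too_few_windows(self):
        with pytest.raises(ValueError, match="10"):
            state_expression([np.arange(5.0)], [np.arange(5.0)])

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            state_expression([np.arange(12.0)], [np.arange(11.0)])


class TestGroupCompare:
    def test_textbook_value(self):
        # pooled t for {1,2,3} vs {2,3,4}: t = -1 / sqrt(2/3)
        t, p = group_compare(np.array([1.0, 2.0, 3.0]),
                             np.array([2.0, 3.0, 4.0]))
        assert t == pytest.approx(-np.sqrt(1.5), abs=1e-10)

    def test_identical_groups(self):
        t, p = group_compare(np.array([1.0, 2.0]), np.array([1.0, 2.0]))
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_too_small(self):
        with pytest.raises(ValueError):
            group_compare(np.array([1.0]), np.array([1.0, 2.0]))


class TestPartialCorrelation:
    def test_no_covariates_is_pearson(self, rng):
        x, y = rng.normal(size=60), rng.normal(size=60)
        r, p = partial_correlation(x, y)
        from scipy import stats
        rr, pp = stats.pearsonr(x, y)
        assert r == pytest.approx(rr, abs=1e-10)
        assert p == pytest.approx(pp, abs=1e-8)

    def test_matches_pingouin(self, rng):
        import pandas as pd
        x = rng.normal(size=80)
        z1, z2 = rng.normal(size=80), rng.normal(size=80)
        y = 0.5 * x + 0.7 * z1 + rng.normal(size=80)
        r, p = partial_correlation(x, y, np.column_stack([z1, z2]))
        df = pd.DataFrame({"x": x, "y": y, "z1": z1, "z2": z2})
        out = pingouin.partial_corr(df, x="x", y="y", covar=["z1", "z2"])
        assert r == pytest.approx(float(out["r"].iloc[0]), abs=1e-8)
        assert p == pytest.approx(float(out["p_val"].iloc[0]), abs=1e-8)

    def test_common_driver_removed(self, rng):
        """x and y both driven by age: raw r is large, partial r near zero."""
        n = 200
        age = rng.normal(size=n)
        x = age + 0.5 * rng.normal(size=n)
        y = age + 0.5 * rng.normal(size=n)
        raw = np.corrcoef(x, y)[0, 1]
        part, _ = partial_correlation(x, y, age)
        assert raw > 0.5
        assert abs(part) < 0.2

    def test_rank_deficient_covariates(self, rng):
        z = rng.normal(size=30)
        with pytest.raises(ValueError, match="rank"):
            partial_correlation(rng.normal(size=30), rng.normal(size=30),
                                np.column_stack([z, 2.0 * z]))


class TestConditionFoCompare:
    def test_hand_computed_anova(self):
        # 3 subjects x 3 conditions, worked by hand / cross-checked below
        X = np.array([[1.0, 2.0, 3.0],
                      [2.0, 2.0, 4.0],
                      [3.0, 4.0, 5.0]])
        res = condition_fo_compare(X)
        grand = X.mean()
        ss_cond = 3 * ((X.mean(axis=0) - grand) ** 2).sum()
        ss_subj = 3 * ((X.mean(axis=1) - grand) ** 2).sum()
        ss_err = ((X - grand) ** 2).sum() - ss_cond - ss_subj
        F = (ss_cond / 2) / (ss_err / 4)
        assert res.F == pytest.approx(F, abs=1e-10)
        assert res.df == (2, 4)

    def test_matches_pingouin_rm_anova(self, rng):
        import pandas as pd
        X = rng.normal(size=(12, 4)) + np.array([0.0, 0.1, 0.2, 0.0])
        res = condition_fo_compare(X)
        long = pd.DataFrame({
            "subj": np.repeat(np.arange(12), 4),
            "cond": np.tile(np.arange(4), 12),
            "y": X.ravel()})
        out = pingouin.rm_anova(long, dv="y", within="cond", subject="subj")
        assert res.F == pytest.approx(float(out["F"].iloc[0]), abs=1e-8)
        assert res.p == pytest.approx(float(out["p_unc"].iloc[0]), abs=1e-8)

    def test_identical_conditions_f_zero(self, rng):
        col = rng.normal(size=10)
        res = condition_fo_compare(np.column_stack([col, col, col]))
        assert res.F == 0.0 and res.p == 1.0

    def test_power_with_planted_shift(self, rng):
        """+0.1 occupancy shift in one of three conditions, n=30, SD 0.05:
        the omnibus test should reach p < 0.01 in at least 90% of runs."""
        hits = 0
        n_rep = 20
        for _ in range(n_rep):
            X = rng.normal(0.3, 0.05, size=(30, 3))
            X[:, 1] += 0.1
            hits += condition_fo_compare(X).p < 0.01
        assert hits >= int(0.9 * n_rep)

    def test_missing_subjects_dropped(self, rng):
        X = rng.normal(size=(6, 3))
        X[2, 1] = np.nan
        res = condition_fo_compare(X)
        assert res.n_subjects == 5

    def test_pairwise_table(self, rng):
        res = condition_fo_compare(rng.normal(size=(8, 3)),
                                   conditions=["a", "b", "c"])
        assert len(res.pairwise) == 3
        assert set(res.pairwise.columns) >= {"a", "b", "t", "p", "significant"}


class TestMediation:
    def test_path_identity(self, rng):
        """a*b + c' must equal the total effect c exactly (OLS identity)."""
        n = 60
        X = rng.normal(size=n)
        M = 0.5 * X + rng.normal(size=n)
        Y = 0.4 * M + 0.2 * X + rng.normal(size=n)
        res = mediation_bca(X, M, Y, B=50, seed=0)
        assert res.a * res.b + res.c_prime == pytest.approx(res.c, abs=1e-10)

    def test_path_identity_with_covariates(self, rng):
        n = 80
        C = rng.normal(size=(n, 2))
        X = rng.normal(size=n) + C[:, 0]
        M = 0.5 * X + rng.normal(size=n)
        Y = 0.4 * M + rng.normal(size=n) + C[:, 1]
        res = mediation_bca(X, M, Y, covariates=C, B=50, seed=0)
        assert res.a * res.b + res.c_prime == pytest.approx(res.c, abs=1e-10)

    def test_near_deterministic_chain(self, rng):
        # exact M = X would be collinear in the Y ~ X + M model, so use a
        # chain with tiny independent noise
        X = rng.normal(size=200)
        M = X + rng.normal(0, 0.1, 200)
        Y = M + rng.normal(0, 1e-3, 200)
        res = mediation_bca(X, M, Y, B=100, seed=0)
        assert res.a == pytest.approx(1.0, abs=0.05)
        assert res.b == pytest.approx(1.0, abs=1e-3)
        assert res.c == pytest.approx(1.0, abs=0.05)
        assert res.c_prime == pytest.approx(0.0, abs=1e-3)
        assert res.indirect == pytest.approx(res.c - res.c_prime, abs=1e-10)

    def test_paths_match_pingouin(self, rng):
        import pandas as pd
        n = 100
        X = rng.normal(size=n)
        M = 0.5 * X + rng.normal(size=n)
        Y = 0.5 * M + 0.2 * X + rng.normal(size=n)
        res = mediation_bca(X, M, Y, B=100, seed=0)
        df = pd.DataFrame({"X": X, "M": M, "Y": Y})
        out = pingouin.mediation_analysis(df, x="X", m="M", y="Y", seed=0,
                                          n_boot=100)
        coef = dict(zip(out["path"], out["coef"]))
        assert res.c == pytest.approx(float(coef["Total"]), abs=1e-8)
        assert res.c_prime == pytest.approx(float(coef["Direct"]), abs=1e-8)
        assert res.indirect == pytest.approx(float(coef["Indirect"]), abs=1e-8)

    def test_batched_bootstrap_matches_loop(self, rng):
        """The vectorized bootstrap must agree with per-replicate OLS."""
        from statecue.association import _batched_paths, _paths
        n = 25
        X = rng.normal(size=n)
        M = 0.5 * X + rng.normal(size=n)
        Y = 0.5 * M + rng.normal(size=n)
        C = rng.normal(size=(n, 1))
        idx = rng.integers(0, n, size=(8, n))
        ind, cp = _batched_paths(X, M, Y, C, idx)
        for b in range(8):
            sel = idx[b]
            ai, bi, _, cpi = _paths(X[sel], M[sel], Y[sel], C[sel])
            assert ind[b] == pytest.approx(ai * bi, abs=1e-6)
            assert cp[b] == pytest.approx(cpi, abs=1e-6)

    def test_degenerate_zero_variance(self):
        X = np.arange(12.0)
        M = np.zeros(12)
        with np.errstate(all="ignore"):
            res = mediation_bca(X, M, M, B=50, seed=0)
        assert res.degenerate
        assert not res.significant

    def test_nan_rejected(self, rng):
        X = rng.normal(size=12)
        X[0] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            mediation_bca(X, np.ones(12), np.ones(12))

    def test_too_few_cases(self, rng):
        with pytest.raises(ValueError, match="10"):
            mediation_bca(rng.normal(size=5), rng.normal(size=5),
                          rng.normal(size=5))

    def test_planted_effect_detected(self, rng):
        n = 200
        X = rng.normal(size=n)
        M = 0.5 * X + rng.normal(size=n)
        Y = 0.5 * M + rng.normal(size=n)
        res = mediation_bca(X, M, Y, B=1000, seed=3)
        assert res.significant
        assert res.ci_low > 0
        assert res.indirect == pytest.approx(0.25, abs=0.1)

    def test_reproducible(self, rng):
        n = 40
        X = rng.normal(size=n)
        M = 0.5 * X + rng.normal(size=n)
        Y = 0.5 * M + rng.normal(size=n)
        r1 = mediation_bca(X, M, Y, B=200, seed=7)
        r2 = mediation_bca(X, M, Y, B=200, seed=7)
        assert (r1.ci_low, r1.ci_high) == (r2.ci_low, r2.ci_high)
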