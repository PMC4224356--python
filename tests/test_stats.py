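"""Statistical primitives: correlation, Box-Cox, regression diagnostics,
exact and classical tests."""

import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps

from epirecomb.errors import DegenerateInputError, InvalidParameterError, UnderdeterminedError
from epirecomb.stats import (
    backward_stepwise,
    boxcox,
    fisher_exact_2x2,
    one_way_anova,
    ols_standardized,
    pearson,
    two_sample_t,
    vif,
)


class TestPearson:
    def test_perfect_linear(self):
        assert pearson([1, 2, 3], [2, 4, 6]).r == pytest.approx(1.0)
        assert pearson([1, 2, 3], [3, 2, 1]).r == pytest.approx(-1.0)

    def test_affine_invariance(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=100)
        y = rng.normal(size=100)
        r0 = pearson(x, y).r
        assert pearson(3 * x + 7, y).r == pytest.approx(r0)
        assert pearson(x, 0.1 * y - 2).r == pytest.approx(r0)

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateInputError):
            pearson([1, 1, 1], [1, 2, 3])

    def test_p_close_to_permutation_p(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=50)
        y = 0.3 * x + rng.normal(size=50)
        res = pearson(x, y)
        # permutation oracle: distribution of |r| under shuffled pairing
        B = 100_000
        xc = x - x.mean()
        yc = y - y.mean()
        perms = rng.permuted(np.tile(yc, (B, 1)), axis=1)
        rs = (perms @ xc) / (np.linalg.norm(xc) * np.linalg.norm(yc))
        p_perm = (1 + np.sum(np.abs(rs) >= abs(res.r))) / (B + 1)
        assert abs(res.p - p_perm) < 0.02


class TestBoxCox:
    def test_lambda_one_is_identity_minus_one(self):
        y, spec = boxcox(np.array([1.0, 2.0, 3.0]), lmbda=1)
        assert np.allclose(y, [0, 1, 2])
        assert spec.lmbda == 1

    def test_lambda_zero_is_log(self):
        y, _ = boxcox(np.array([1.0, math.e]), lmbda=0)
        assert np.allclose(y, [0, 1])

    def test_auto_lambda_near_zero_for_lognormal(self):
        rng = np.random.default_rng(11)
        x = np.exp(rng.normal(size=10_000))
        _, spec = boxcox(x, lmbda="auto")
        assert abs(spec.lmbda) < 0.1

    def test_auto_lambda_near_one_for_normal(self):
        rng = np.random.default_rng(12)
        x = rng.normal(10, 1, size=10_000)
        _, spec = boxcox(x, lmbda="auto")
        assert 0.5 <= spec.lmbda <= 1.5

    def test_zero_handling_shift(self):
        x = np.array([0.0, 1.0, 2.0, 4.0])
        _, spec = boxcox(x, lmbda=0.5)
        assert spec.shift == pytest.approx(0.5)  # half the smallest positive

    def test_negative_without_shift_rejected(self):
        with pytest.raises(InvalidParameterError):
            boxcox(np.array([-1.0, 2.0]), lmbda=1)


class TestVif:
    def test_uncorrelated_predictors_near_one(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(5_000, 2))
        assert np.allclose(vif(X), 1.0, atol=0.05)

    def test_closed_form_two_predictors(self):
        rng = np.random.default_rng(3)
        x1 = rng.normal(size=2_000)
        x2 = 0.6 * x1 + np.sqrt(1 - 0.36) * rng.normal(size=2_000)
        X = np.c_[x1, x2]
        r = np.corrcoef(x1, x2)[0, 1]
        expect = 1.0 / (1.0 - r**2)
        assert np.allclose(vif(X), expect, atol=1e-6)

    def test_duplicate_predictor_infinite(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=100)
        with pytest.warns(UserWarning):
            v = vif(np.c_[x, x])
        assert np.isinf(v).all()


class TestOlsStandardized:
    def test_exact_fit(self):
        x = np.arange(50.0)
        res = ols_standardized(x, x[:, None])
        assert res.standardized_beta["x0"] == pytest.approx(1.0)
        assert res.adjusted_r2 == pytest.approx(1.0)

    def test_null_betas_small(self):
        rng = np.random.default_rng(5)
        y = rng.normal(size=10_000)
        X = rng.normal(size=(10_000, 2))
        res = ols_standardized(y, X)
        assert all(abs(b) < 0.05 for b in res.standardized_beta.values())
        assert res.adjusted_r2 < 0.01

    def test_beta_invariant_to_rescaling(self):
        rng = np.random.default_rng(6)
        X = pd.DataFrame({"a": rng.normal(size=500), "b": rng.normal(size=500)})
        y = X["a"] * 2 + rng.normal(size=500)
        r1 = ols_standardized(y, X)
        X2 = X.copy()
        X2["a"] = X2["a"] * 1_000
        r2 = ols_standardized(y, X2)
        for k in ("a", "b"):
            assert r1.standardized_beta[k] == pytest.approx(r2.standardized_beta[k])

    def test_listwise_nan_deletion(self):
        rng = np.random.default_rng(7)
        y = rng.normal(size=100)
        X = pd.DataFrame({"a": rng.normal(size=100)})
        X.iloc[0, 0] = np.nan
        assert ols_standardized(y, X).nobs == 99

    def test_underdetermined(self):
        with pytest.raises(UnderdeterminedError):
            ols_standardized([1.0, 2.0], np.array([[1.0], [2.0]]))


class TestBackwardStepwise:
    def test_retains_only_planted_predictor(self):
        rng = np.random.default_rng(8)
        n = 500
        x1 = rng.normal(size=n)
        x2 = rng.normal(size=n)
        y = x1 + 0.1 * rng.normal(size=n)
        res = backward_stepwise(y, pd.DataFrame({"x1": x1, "x2": x2}))
        assert res.retained == ["x1"] and res.dropped == ["x2"]

    def test_single_significant_predictor_matches_plain_fit(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=200)
        y = 0.8 * x + rng.normal(size=200)
        full = ols_standardized(y, pd.DataFrame({"x": x}))
        step = backward_stepwise(y, pd.DataFrame({"x": x}))
        assert step.standardized_beta == full.standardized_beta

    def test_pure_noise_usually_retains_nothing(self):
        empty = 0
        for seed in range(50):
            rng = np.random.default_rng(1_000 + seed)
            X = pd.DataFrame(rng.normal(size=(200, 2)), columns=["a", "b"])
            res = backward_stepwise(rng.normal(size=200), X)
            empty += res.retained == []
        assert empty >= 45  # ~ (1 - alpha)^... of seeds

    def test_aic_criterion_also_drops_noise(self):
        rng = np.random.default_rng(10)
        n = 500
        x1 = rng.normal(size=n)
        x2 = rng.normal(size=n)
        y = x1 + 0.1 * rng.normal(size=n)
        res = backward_stepwise(y, pd.DataFrame({"x1": x1, "x2": x2}), criterion="aic")
        assert "x1" in res.retained and "x2" not in res.retained


def _fisher_enumeration_oracle(a, b, c, d):
    """Brute force: enumerate all tables with the observed margins and sum
    hypergeometric probabilities <= the observed one."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    lo, hi = max(0, c1 - r2), min(r1, c1)
    pmf = sps.hypergeom.pmf(np.arange(lo, hi + 1), n, r1, c1)
    obs = pmf[a - lo]
    return float(pmf[pmf <= obs * (1 + 1e-12)].sum())


class TestFisherExact:
    def test_small_enumerations(self):
        assert fisher_exact_2x2([[2, 0], [0, 2]]) == pytest.approx(1 / 3)
        assert fisher_exact_2x2([[5, 5], [5, 5]]) == pytest.approx(1.0)
        assert fisher_exact_2x2([[10, 0], [0, 10]]) == pytest.approx(2 / math.comb(20, 10))

    def test_matches_enumeration_oracle_random_tables(self):
        rng = np.random.default_rng(13)
        for _ in range(200):
            t = rng.integers(0, 15, size=4)
            a, b, c, d = (int(v) for v in t)
            if min(a + b, c + d, a + c, b + d) == 0:
                continue
            assert fisher_exact_2x2([[a, b], [c, d]]) == pytest.approx(
                _fisher_enumeration_oracle(a, b, c, d), rel=1e-9
            )

    def test_matches_scipy_on_large_table(self):
        table = [[816, 9_300 - 816], [229, 9_300 - 229]]
        assert fisher_exact_2x2(table) == pytest.approx(
            sps.fisher_exact(table)[1], rel=1e-9
        )

    def test_zero_margin_rejected(self):
        with pytest.raises(DegenerateInputError):
            fisher_exact_2x2([[0, 0], [1, 2]])


class TestTTestAnova:
    def test_identical_samples(self):
        x = [1.0, 2.0, 3.0]
        t, p = two_sample_t(x, x)
        assert t == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_overwhelming_separation(self):
        rng = np.random.default_rng(14)
        _, p = two_sample_t(rng.normal(0, 1, 100), rng.normal(5, 1, 100))
        assert p < 1e-9

    def test_welch_close_to_permutation(self):
        # equal group sizes: the Welch p and the label-permutation p estimate
        # the same tail probability (with unequal n AND unequal variances
        # the permutation null answers a different question)
        rng = np.random.default_rng(15)
        n = 50
        x = rng.normal(0, 1, size=n)
        y = rng.normal(0.4, 2.0, size=n)
        _, p = two_sample_t(x, y)
        pooled = np.r_[x, y]
        B = 20_000
        diffs = np.empty(B)
        for i in range(B):
            rng.shuffle(pooled)
            diffs[i] = pooled[:n].mean() - pooled[n:].mean()
        p_perm = (1 + np.sum(np.abs(diffs) >= abs(x.mean() - y.mean()))) / (B + 1)
        assert abs(p - p_perm) < 0.02

    def test_identical_groups_f_zero(self):
        g = [1.0, 2.0, 3.0]
        f, p = one_way_anova([g, g, g])
        assert f == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_two_group_anova_equals_pooled_t_squared(self):
        rng = np.random.default_rng(16)
        x = rng.normal(size=30)
        y = rng.normal(0.5, 1, size=25)
        f, p_f = one_way_anova([x, y])
        t, p_t = sps.ttest_ind(x, y, equal_var=True)
        assert f == pytest.approx(t**2)
        assert p_f == pytest.approx(p_t)

    def test_type_i_error_calibrated(self):
        rng = np.random.default_rng(17)
        runs = 10_000
        # vectorized: F statistic for 3 groups of n=30 across all runs
        g = rng.normal(size=(runs, 3, 30))
        gm = g.mean(axis=2)
        grand = g.mean(axis=(1, 2))
        ssb = 30 * ((gm - grand[:, None]) ** 2).sum(axis=1)
        ssw = ((g - gm[:, :, None]) ** 2).sum(axis=(1, 2))
        F = (ssb / 2) / (ssw / (90 - 3))
        crit = sps.f.ppf(0.95, 2, 87)
        rate = np.mean(F > crit)
        assert 0.04 <= rate <= 0.06
        # spot-check the vectorized statistic against the implementation
        f0, _ = one_way_anova(list(g[0]))
        assert f0 == pytest.approx(F[0])
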