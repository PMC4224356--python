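"""Statistical primitives for the window- and hotspot-scale analyses.

Most primitives are thin, validated fronts over SciPy / statsmodels (Pearson
correlation, Box–Cox, OLS, Welch t, one-way ANOVA).  The 2x2 exact test is
implemented in-package with exact integer hypergeometric enumeration so that
probability-mass ties are resolved exactly rather than with floating-point
fuzz; SciPy's implementation serves as an independent cross-check in the test
suite.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm

from .errors import DegenerateInputError, InvalidParameterError, UnderdeterminedError

__all__ = [
    "CorrelationResult",
    "TransformSpec",
    "RegressionResult",
    "pearson",
    "boxcox",
    "vif",
    "ols_standardized",
    "backward_stepwise",
    "fisher_exact_2x2",
    "two_sample_t",
    "one_way_anova",
]


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    n: int


@dataclass(frozen=True)
class TransformSpec:
    """A fitted Box–Cox transform: exponent ``lmbda`` applied after adding
    ``shift`` (used to clear zeros; all shifted values must be positive)."""

    lmbda: float
    shift: float = 0.0

    def apply(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float) + self.shift
        if np.any(x <= 0):
            raise InvalidParameterError("non-positive values after shift")
        if self.lmbda == 0:
            return np.log(x)
        return (np.power(x, self.lmbda) - 1.0) / self.lmbda


@dataclass
class RegressionResult:
    """Standardized OLS fit: per-predictor standardized coefficients (beta),
    p-values and variance inflation factors, plus adjusted R^2 and the set of
    retained predictors (equal to all supplied predictors unless stepwise
    selection removed some)."""

    standardized_beta: dict[str, float]
    pvalues: dict[str, float]
    vif: dict[str, float]
    adjusted_r2: float
    retained: list[str]
    nobs: int
    dropped: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "predictor": k,
                "beta": self.standardized_beta[k],
                "p": self.pvalues[k],
                "vif": self.vif.get(k, np.nan),
            }
            for k in self.retained
        ]
        return pd.DataFrame(rows, columns=["predictor", "beta", "p", "vif"])


def pearson(x, y) -> CorrelationResult:
    """Sample Pearson correlation with the classical t-distribution (n-2 df)
    two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InvalidParameterError("x and y must be 1-D vectors of equal length")
    if len(x) < 3:
        raise InvalidParameterError("need at least 3 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DegenerateInputError("zero variance in correlation input")
    r, p = sps.pearsonr(x, y)
    return CorrelationResult(float(r), float(p), len(x))


_BOXCOX_GRID = np.round(np.arange(-3.0, 3.0 + 1e-9, 0.01), 2)


def boxcox(x, lmbda: float | str = "auto", shift: float | None = None):
    """Box–Cox power transform.

    ``lmbda="auto"`` maximizes the profile log-likelihood over a grid
    (-3..3, step 0.01).  When ``shift`` is None, a shift of half the smallest
    positive value is applied if zeros are present (recombination rates can
    be exactly zero); strictly negative input requires an explicit shift.
    Returns ``(transformed, TransformSpec)``.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or len(x) == 0:
        raise InvalidParameterError("x must be a nonempty 1-D vector")
    if shift is None:
        if np.any(x < 0):
            raise InvalidParameterError("negative values require an explicit shift")
        shift = 0.0
        if np.any(x == 0):
            pos = x[x > 0]
            if len(pos) == 0:
                raise DegenerateInputError("all values zero; Box-Cox undefined")
            shift = float(pos.min()) / 2.0
    xs = x + shift
    if np.any(xs <= 0):
        raise InvalidParameterError("non-positive values after shift")
    if lmbda == "auto":
        llf = np.array([sps.boxcox_llf(l, xs) for l in _BOXCOX_GRID])
        lmbda = float(_BOXCOX_GRID[int(np.argmax(llf))])
    spec = TransformSpec(lmbda=float(lmbda), shift=float(shift))
    return spec.apply(x), spec


def _as_matrix(predictors) -> tuple[np.ndarray, list[str]]:
    if isinstance(predictors, pd.DataFrame):
        return predictors.to_numpy(dtype=float), [str(c) for c in predictors.columns]
    X = np.asarray(predictors, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return X, [f"x{i}" for i in range(X.shape[1])]


def vif(predictors) -> np.ndarray:
    """Variance inflation factor per predictor: 1 / (1 - R^2_j), with R^2_j
    from regressing predictor j on the others (with intercept).

    A single predictor has VIF 1 by convention; exact collinearity is
    reported as ``inf`` with a warning.
    """
    X, names = _as_matrix(predictors)
    n, p = X.shape
    if p >= 1 and n <= p:
        raise UnderdeterminedError("need more rows than predictors for VIF")
    if p == 1:
        return np.array([1.0])
    out = np.empty(p)
    for j in range(p):
        others = sm.add_constant(np.delete(X, j, axis=1))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r2 = sm.OLS(X[:, j], others).fit().rsquared
        if r2 >= 1.0 - 1e-12:
            warnings.warn(f"predictor {names[j]!r} is exactly collinear; VIF infinite")
            out[j] = np.inf
        else:
            out[j] = 1.0 / (1.0 - r2)
    return out


def _zscore(a: np.ndarray) -> np.ndarray:
    sd = a.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise DegenerateInputError("constant column cannot be standardized")
    return (a - a.mean(axis=0)) / sd


def ols_standardized(response, predictors) -> RegressionResult:
    """OLS on z-scored response and predictors.

    Rows with any undefined value are dropped listwise.  Reports standardized
    coefficients (comparable across predictors regardless of units),
    two-sided p-values, adjusted R^2 and per-predictor VIFs.
    """
    y = np.asarray(response, dtype=float)
    X, names = _as_matrix(predictors)
    if y.ndim != 1 or len(y) != X.shape[0]:
        raise InvalidParameterError("response and predictors must align")
    keep = np.isfinite(y) & np.all(np.isfinite(X), axis=1)
    y, X = y[keep], X[keep]
    n, p = X.shape
    if n <= p + 1:
        raise UnderdeterminedError(f"n={n} too small for {p} predictors")
    zy = _zscore(y)
    zX = _zscore(X)
    model = sm.OLS(zy, sm.add_constant(zX)).fit()
    betas = dict(zip(names, model.params[1:]))
    pvals = dict(zip(names, model.pvalues[1:]))
    vifs = dict(zip(names, vif(pd.DataFrame(zX, columns=names))))
    return RegressionResult(
        standardized_beta={k: float(v) for k, v in betas.items()},
        pvalues={k: float(v) for k, v in pvals.items()},
        vif={k: float(v) for k, v in vifs.items()},
        adjusted_r2=float(model.rsquared_adj),
        retained=list(names),
        nobs=int(n),
    )


def backward_stepwise(response, predictors, alpha: float = 0.05, criterion: str = "pvalue") -> RegressionResult:
    """Backward stepwise selection on the standardized model.

    ``criterion="pvalue"`` (default): iteratively refit, removing the
    predictor with the largest p-value while that p exceeds ``alpha``.
    ``criterion="aic"``: remove the predictor whose removal most lowers the
    AIC while any removal lowers it.  Returns the final fit; with every
    predictor removed, an empty result (adjusted R^2 0, no coefficients).
    """
    y = np.asarray(response, dtype=float)
    X, names = _as_matrix(predictors)
    df = pd.DataFrame(X, columns=names)
    dropped: list[str] = []
    current = list(names)
    while current:
        res = ols_standardized(y, df[current])
        if criterion == "pvalue":
            worst = max(current, key=lambda k: res.pvalues[k])
            if res.pvalues[worst] <= alpha:
                break
            current.remove(worst)
            dropped.append(worst)
        elif criterion == "aic":
            keep_n = np.isfinite(y) & np.all(np.isfinite(df[current].to_numpy()), axis=1)
            base_aic = sm.OLS(
                _zscore(y[keep_n]), sm.add_constant(_zscore(df.loc[keep_n, current].to_numpy()))
            ).fit().aic
            best_k, best_aic = None, base_aic
            for k in current:
                rest = [c for c in current if c != k]
                if not rest:
                    zres = _zscore(y[keep_n])
                    cand = sm.OLS(zres, np.ones((len(zres), 1))).fit().aic
                else:
                    cand = sm.OLS(
                        _zscore(y[keep_n]),
                        sm.add_constant(_zscore(df.loc[keep_n, rest].to_numpy())),
                    ).fit().aic
                if cand < best_aic:
                    best_k, best_aic = k, cand
            if best_k is None:
                break
            current.remove(best_k)
            dropped.append(best_k)
        else:
            raise InvalidParameterError(f"unknown criterion {criterion!r}")
    if not current:
        return RegressionResult({}, {}, {}, 0.0, [], int(np.isfinite(y).sum()), dropped)
    res = ols_standardized(y, df[current])
    res.dropped = dropped
    return res


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher's exact test on a 2x2 count table.

    Probability-mass method: sum, over all tables with the observed margins,
    of the hypergeometric probabilities no larger than the observed table's.
    Computed with exact integer arithmetic (ties are exact, not
    floating-point-fuzzy); the final probability is rounded to float once.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or np.any(t < 0):
        raise InvalidParameterError("table must be 2x2 with non-negative integer counts")
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        raise DegenerateInputError("zero margin in 2x2 table")
    n = r1 + r2
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    # numerators share the denominator C(n, c1); compare integers exactly
    nums = [math.comb(r1, k) * math.comb(r2, c1 - k) for k in range(lo, hi + 1)]
    obs = nums[a - lo]
    total = sum(num for num in nums if num <= obs)
    p = Fraction(total, math.comb(n, c1))
    return min(1.0, float(p))


def two_sample_t(x, y) -> tuple[float, float]:
    """Welch's (unequal-variance) two-sample t test, two-sided."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise InvalidParameterError("each sample needs n >= 2")
    t, p = sps.ttest_ind(x, y, equal_var=False)
    return float(t), float(p)


def one_way_anova(groups) -> tuple[float, float]:
    """Classical one-way ANOVA F statistic and p-value."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise InvalidParameterError("need at least 2 groups")
    if any(len(g) < 2 for g in groups):
        raise InvalidParameterError("every group needs n >= 2")
    f, p = sps.f_oneway(*groups)
    return float(f), float(p)
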