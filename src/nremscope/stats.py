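"""Group-statistics layer: Welch and paired t-tests, 3-SD outlier removal,
JZS Bayes factors, Pearson correlations, and moderation regressions.

Tests are two-tailed; independent comparisons assume unequal variances
(Welch-Satterthwaite df).  Outlier removal is a single pass against the mean
and SD of the full input.  Bayes factors use the JZS form -- a Cauchy prior
on the standardized effect with scale r (default 0.5), computed by adaptive
quadrature over the inverse-gamma mixing variable.  No multiple-comparison
correction is applied anywhere in this layer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate, stats as sp_stats
import statsmodels.api as sm

__all__ = [
    "TestResult",
    "CorrelationResult",
    "RegressionResult",
    "welch_t",
    "paired_t",
    "remove_outliers",
    "bf10_ttest",
    "interpret_bf10",
    "pearson_r",
    "moderated_regression",
]


@dataclass
class TestResult:
    statistic: float | None
    df: float | None
    p: float | None
    bf10: float | None
    bf_bin: str | None
    n1: int
    n2: int
    note: str = ""


@dataclass
class CorrelationResult:
    r: float
    statistic: float
    df: int
    p: float


@dataclass
class RegressionResult:
    terms: dict          # name -> {"b": ..., "t": ..., "p": ...}
    df_resid: float
    r_squared: float


def interpret_bf10(bf10: float) -> str:
    """Evidence bin for a BF10 value (<=1 favors the null)."""
    if bf10 <= 1:
        return "null-favoring"
    if bf10 <= 3:
        return "anecdotal"
    if bf10 <= 10:
        return "moderate"
    if bf10 <= 30:
        return "strong"
    if bf10 <= 100:
        return "very strong"
    return "extreme"


def bf10_ttest(t: float, n1: int, n2: int | None = None,
               rscale: float = 0.5) -> float:
    """JZS Bayes factor for a t statistic (two-sample when n2 is given,
    one-sample/paired otherwise), Cauchy prior scale ``rscale``.

    Uses the inverse-gamma(1/2, 1/2) mixture representation of the Cauchy
    prior and adaptive quadrature over the mixing variable g.
    """
    if not np.isfinite(t):
        raise ValueError("non-finite t statistic")
    if n2 is not None:
        n_eff = n1 * n2 / (n1 + n2)
        nu = n1 + n2 - 2
    else:
        n_eff = float(n1)
        nu = n1 - 1
    if nu <= 0:
        raise ValueError("not enough observations for a Bayes factor")
    t2 = t * t
    r2 = rscale * rscale

    def integrand(g):
        a = 1.0 + n_eff * g * r2
        log_f = (-0.5 * np.log(a)
                 - 0.5 * (nu + 1) * np.log1p(t2 / (nu * a))
                 - 0.5 * np.log(2 * np.pi) - 1.5 * np.log(g) - 0.5 / g)
        return np.exp(log_f)

    num, _ = integrate.quad(integrand, 0, np.inf, limit=200)
    log_den = -0.5 * (nu + 1) * np.log1p(t2 / nu)
    return float(num / np.exp(log_den))


def _finish(t: float, df: float, n1: int, n2: int | None) -> TestResult:
    p = float(2 * sp_stats.t.sf(abs(t), df))
    p = max(p, np.finfo(float).tiny)
    bf = bf10_ttest(t, n1, n2)
    return TestResult(statistic=float(t), df=float(df), p=p, bf10=bf,
                      bf_bin=interpret_bf10(bf), n1=n1, n2=n2 if n2 else n1)


def welch_t(x, y) -> TestResult:
    """Two-tailed independent t-test with unequal variances."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    if nx < 2 or ny < 2:
        raise ValueError("need at least 2 observations per group")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    se2 = vx / nx + vy / ny
    if se2 == 0:
        return TestResult(statistic=0.0, df=float(nx + ny - 2), p=1.0,
                          bf10=None, bf_bin=None, n1=nx, n2=ny,
                          note="zero variance in both groups")
    t = (x.mean() - y.mean()) / np.sqrt(se2)
    df = se2 ** 2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    return _finish(t, df, nx, ny)


def paired_t(x, y) -> TestResult:
    """Two-tailed dependent t-test (one-sample t on the differences).

    Zero-variance differences give an absent result with a diagnostic note
    rather than an infinite statistic.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("paired samples must have equal length")
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0:
        return TestResult(statistic=None, df=None, p=None, bf10=None,
                          bf_bin=None, n1=n, n2=n,
                          note="degenerate: zero variance of differences")
    t = d.mean() / (sd / np.sqrt(n))
    return _finish(t, n - 1, n, None)


def remove_outliers(x, k: float = 3.0):
    """Single-pass removal of values more than k SDs from the mean.

    Mean and SD are computed on the full input; constant input (SD = 0)
    removes nothing.  Returns (kept values, removed indices).
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 values")
    sd = x.std(ddof=1)
    if sd == 0:
        return x.copy(), np.array([], dtype=int)
    removed = np.flatnonzero(np.abs(x - x.mean()) > k * sd)
    kept = np.delete(x, removed)
    return kept, removed


def pearson_r(x, y) -> CorrelationResult:
    """Pearson correlation with t = r*sqrt((n-2)/(1-r^2)), df = n-2."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("constant input has no defined correlation")
    xc, yc = x - x.mean(), y - y.mean()
    r = float(np.dot(xc, yc) / np.sqrt(np.dot(xc, xc) * np.dot(yc, yc)))
    r = float(np.clip(r, -1.0, 1.0))
    df = n - 2
    if abs(r) == 1.0:
        return CorrelationResult(r=r, statistic=float(np.inf * np.sign(r)),
                                 df=df, p=0.0)
    t = r * np.sqrt(df / (1.0 - r * r))
    return CorrelationResult(r=r, statistic=float(t), df=df,
                             p=float(2 * sp_stats.t.sf(abs(t), df)))


def moderated_regression(y, x, moderator) -> RegressionResult:
    """OLS of y on x, the moderator, and their product term."""
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    m = np.asarray(moderator, dtype=float)
    n = len(y)
    if not (len(x) == len(m) == n):
        raise ValueError("y, x, moderator must have equal length")
    if n <= 4:
        raise ValueError("need more than 4 observations")
    design = sm.add_constant(np.column_stack([x, m, x * m]), has_constant="add")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("rank-deficient design (collinear predictors)")
    names = ["intercept", "x", "moderator", "interaction"]
    if np.ptp(y) == 0:
        # degenerate response: flat fit, no explained variance
        terms = {name: {"b": float(y[0]) if name == "intercept" else 0.0,
                        "t": 0.0, "p": 1.0} for name in names}
        return RegressionResult(terms=terms, df_resid=float(n - 4), r_squared=0.0)
    fit = sm.OLS(y, design).fit()
    terms = {name: {"b": float(b), "t": float(t), "p": float(p)}
             for name, b, t, p in zip(names, fit.params, fit.tvalues, fit.pvalues)}
    return RegressionResult(terms=terms, df_resid=float(fit.df_resid),
                            r_squared=float(fit.rsquared))
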