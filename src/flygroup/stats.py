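"""Statistical comparisons: Brunner-Munzel, paired t, assumption checks.

Comparisons between conditions use the Brunner-Munzel rank test (robust to
non-normality and unequal variances) or the paired t-test, after checking
variance equality (two-sided F ratio) and normality (Shapiro-Wilk).  Effect
sizes are Cohen's d with pooled (n-1)-denominator standard deviations; the
convention is stated here because published d values depend on it.
"""

from __future__ import annotations

import math

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str
    df: float | None = None
    effect_size_d: float | None = None
    relative_effect: float | None = None

    def __post_init__(self) -> None:
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value outside [0, 1]")


def _asarray(x) -> np.ndarray:
    a = np.asarray(x, dtype=float).ravel()
    if a.size == 0:
        raise ValueError("empty sample")
    return a


def cohens_d(x, y) -> float:
    """|mean(x) - mean(y)| / pooled s.d. (n-1 denominators)."""
    x, y = _asarray(x), _asarray(y)
    nx, ny = x.size, y.size
    pooled = np.sqrt(
        ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    )
    if pooled == 0:
        raise ValueError("zero pooled variance")
    return float(abs(x.mean() - y.mean()) / pooled)


def relative_effect(x, y) -> float:
    """P(X < Y) + 0.5 P(X = Y): the Brunner-Munzel stochastic tendency."""
    x, y = _asarray(x), _asarray(y)
    less = (x[:, None] < y[None, :]).mean()
    ties = (x[:, None] == y[None, :]).mean()
    return float(less + 0.5 * ties)


def brunner_munzel(x, y) -> TestResult:
    """Two-sided Brunner-Munzel test with the t approximation.

    The statistic is positive when the stochastic tendency favours ``y``
    (P(X < Y) > 1/2), so it is antisymmetric in the argument order.

    Under complete separation the rank variances vanish and the t
    approximation is undefined; the statistic is then +/-inf and the
    p-value falls back to the most extreme two-sided permutation value,
    ``2 / C(n+m, n)``.
    """
    x, y = _asarray(x), _asarray(y)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least 2 values")
    if np.unique(np.concatenate([x, y])).size == 1:
        raise ValueError("all values tied: Brunner-Munzel undefined")
    nx, ny = x.size, y.size
    p_hat = relative_effect(x, y)
    rank_all = sps.rankdata(np.concatenate([x, y]))
    rx, ry = rank_all[:nx], rank_all[nx:]
    sx2 = np.var(rx - sps.rankdata(x), ddof=1)
    sy2 = np.var(ry - sps.rankdata(y), ddof=1)
    if sx2 == 0 and sy2 == 0:  # complete separation
        return TestResult(
            statistic=float(np.copysign(np.inf, p_hat - 0.5)),
            p_value=min(1.0, 2.0 / math.comb(nx + ny, nx)),
            method="brunner_munzel",
            df=None,
            effect_size_d=None,
            relative_effect=p_hat,
        )
    res = sps.brunnermunzel(x, y, alternative="two-sided", distribution="t")
    # Satterthwaite df as used by the t approximation.
    num = (nx * sx2 + ny * sy2) ** 2
    den = (nx * sx2) ** 2 / (nx - 1) + (ny * sy2) ** 2 / (ny - 1)
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        method="brunner_munzel",
        df=float(num / den),
        effect_size_d=None,
        relative_effect=p_hat,
    )


def paired_t(x, y) -> TestResult:
    """Classical two-sided paired t-test with Cohen's d effect size."""
    x, y = _asarray(x), _asarray(y)
    if x.size != y.size:
        raise ValueError("paired samples must have equal length")
    if x.size < 2:
        raise ValueError("need at least 2 pairs")
    d = x - y
    if np.var(d, ddof=1) == 0:
        raise ValueError("differences have zero variance")
    res = sps.ttest_rel(x, y)
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        method="paired_t",
        df=float(x.size - 1),
        effect_size_d=cohens_d(x, y),
    )


def f_var_test(x, y) -> TestResult:
    """Two-sided F test of variance equality (ratio of sample variances)."""
    x, y = _asarray(x), _asarray(y)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least 2 values")
    vy = y.var(ddof=1)
    if vy == 0:
        raise ValueError("zero variance in second sample")
    f = x.var(ddof=1) / vy
    dfx, dfy = x.size - 1, y.size - 1
    cdf = sps.f.cdf(f, dfx, dfy)
    p = 2 * min(cdf, 1 - cdf)
    return TestResult(statistic=float(f), p_value=float(min(p, 1.0)),
                      method="f_var", df=float(dfx))


def shapiro_wilk(x) -> TestResult:
    """Shapiro-Wilk normality test for one sample."""
    x = _asarray(x)
    if x.size < 3:
        raise ValueError("Shapiro-Wilk needs at least 3 values")
    res = sps.shapiro(x)
    return TestResult(statistic=float(res.statistic), p_value=float(res.pvalue),
                      method="shapiro_wilk")


@dataclass
class AssumptionReport:
    f_test: TestResult
    shapiro_x: TestResult
    shapiro_y: TestResult
    alpha: float
    recommended: str  # "t_test" | "brunner_munzel"


def assumption_checks(x, y, alpha: float = 0.05) -> AssumptionReport:
    """Variance-equality and normality checks guiding the test choice.

    Recommends the Brunner-Munzel test when either the F test or a
    Shapiro-Wilk test rejects at ``alpha``; a t-based comparison otherwise.
    """
    f = f_var_test(x, y)
    sx = shapiro_wilk(x)
    sy = shapiro_wilk(y)
    fails = (f.p_value < alpha) or (sx.p_value < alpha) or (sy.p_value < alpha)
    return AssumptionReport(
        f_test=f,
        shapiro_x=sx,
        shapiro_y=sy,
        alpha=alpha,
        recommended="brunner_munzel" if fails else "t_test",
    )
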