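"""Serial t-tests for N-of-1 trials, and their usual t-test analogues.

Four tests are provided, crossing paired vs 2-sample designs with level- vs
rate-change hypotheses. Each computes the ordinary least squares effect
estimate and variance, estimates the serial correlation from the residuals
(bias-corrected), and then evaluates the AR(1) kernels c, b, m' to form

    t = estimate / sqrt(c(r) * s^2 / b(r))

referred to a Student t distribution on the fractional degrees of freedom
m' - p (summed over arms for 2-sample tests). With the correlation forced
to zero every serial test collapses exactly onto its usual analogue.

Minimum series lengths: paired level m >= 4; paired rate m >= 5; 2-sample
level m_A, m_B >= 3 with m_A + m_B >= 7; 2-sample rate m_A, m_B >= 4 with
m_A + m_B >= 9.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .ar1_kernels import Ar1Kernel, ChangeType, ar1_kernel
from .correlation import (
    CorrelationEstimate,
    Design,
    ZeroVarianceError,
    centered_index,
    estimate_serial_r,
    fuller_r,
    level_residuals,
    pooled_r,
    rate_residuals,
    rho_hat_mle,
)

__all__ = [
    "ObservationSeries",
    "PairedDifferenceSeries",
    "SerialTestResult",
    "DegreesOfFreedomError",
    "paired_serial_level",
    "two_sample_serial_level",
    "paired_serial_rate",
    "two_sample_serial_rate",
    "usual_paired_level",
    "usual_two_sample_level",
    "usual_paired_rate",
    "usual_two_sample_rate",
    "p_value_and_ci",
    "screen_change",
]


class DegreesOfFreedomError(ValueError):
    """Estimated effective sample size leaves no error degrees of freedom."""


@dataclass(frozen=True)
class ObservationSeries:
    """One equally spaced series of observations from a single individual."""

    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1:
            raise ValueError("series must be one-dimensional")
        if not np.all(np.isfinite(v)):
            raise ValueError("series contains non-finite values; missing "
                             "observations are not supported")
        object.__setattr__(self, "values", v)

    @property
    def m(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class PairedDifferenceSeries:
    """Within-pair A-B differences, ordered by pair."""

    differences: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.differences, dtype=float)
        if v.ndim != 1 or not np.all(np.isfinite(v)):
            raise ValueError("differences must be a finite 1-d sequence")
        object.__setattr__(self, "differences", v)

    @classmethod
    def from_arms(cls, a: "ObservationSeries", b: "ObservationSeries") -> "PairedDifferenceSeries":
        if a.m != b.m:
            raise ValueError("paired arms must have equal length")
        return cls(a.values - b.values)

    @property
    def m(self) -> int:
        return self.differences.size


@dataclass(frozen=True)
class SerialTestResult:
    design: Design
    estimate: float
    s2: float
    r_used: float | None
    correlation: CorrelationEstimate | None
    kernels: tuple[Ar1Kernel, ...]
    se: float
    df: float
    t: float
    p_one_sided: float
    p_two_sided: float
    ci_level: float
    ci_lower: float
    ci_upper: float
    alternative_direction: str
    n_obs: tuple[int, ...] = field(default=())
    serial: bool = True

    @property
    def low_df(self) -> bool:
        """Degrees of freedom below 1; tail quantiles are extremely heavy."""
        return self.df < 1.0

    def to_dict(self) -> dict:
        d = {
            "design": self.design.value,
            "serial": self.serial,
            "estimate": self.estimate,
            "s": float(np.sqrt(self.s2)),
            "s2": self.s2,
            "r_used": self.r_used,
            "se": self.se,
            "df": self.df,
            "t": self.t,
            "p_one_sided": self.p_one_sided,
            "p_two_sided": self.p_two_sided,
            "alternative_direction": self.alternative_direction,
            "ci_level": self.ci_level,
            "ci_lower": self.ci_lower,
            "ci_upper": self.ci_upper,
            "n_obs": list(self.n_obs),
            "low_df": self.low_df,
        }
        if self.kernels:
            d["kernels"] = [
                {"m": k.m, "c": k.c, "b": k.b, "m_prime": k.m_prime} for k in self.kernels
            ]
        return d


def p_value_and_ci(
    t: float,
    df: float,
    direction: str,
    ci_level: float,
    estimate: float,
    standard_error: float,
) -> tuple[float, float, tuple[float, float]]:
    """Student-t tail probabilities and CI at real-valued degrees of freedom."""
    if df <= 0:
        raise DegreesOfFreedomError(f"degrees of freedom must be positive, got {df}")
    if direction not in ("greater", "less"):
        raise ValueError("direction must be 'greater' or 'less'")
    upper = float(stats.t.sf(t, df))
    lower = float(stats.t.cdf(t, df))
    p_one = upper if direction == "greater" else lower
    p_two = min(1.0, 2.0 * min(upper, lower))
    alpha = 1.0 - ci_level
    q = float(stats.t.ppf(1.0 - alpha / 2.0, df))
    ci = (estimate - q * standard_error, estimate + q * standard_error)
    return p_one, p_two, ci


def _as_values(d) -> np.ndarray:
    if isinstance(d, PairedDifferenceSeries):
        return d.differences
    if isinstance(d, ObservationSeries):
        return d.values
    return np.asarray(d, dtype=float)


def _check_df(df: float) -> None:
    if df <= 0:
        raise DegreesOfFreedomError(
            "effective sample size too small at the estimated correlation "
            f"(DF = {df:.4g} <= 0); collect more observations"
        )


def _build_result(design, estimate, s2, corr, r_used, kernels, df, ci_level,
                  direction, n_obs, serial) -> SerialTestResult:
    se = float(np.sqrt(s2 * sum(k.c / k.b for k in kernels)))
    if se <= 0 or not np.isfinite(se):
        raise ZeroVarianceError("zero variance: test statistic undefined")
    t = estimate / se
    p_one, p_two, (lo, hi) = p_value_and_ci(t, df, direction, ci_level, estimate, se)
    return SerialTestResult(
        design=design, estimate=float(estimate), s2=float(s2), r_used=r_used,
        correlation=corr, kernels=tuple(kernels), se=se, df=float(df), t=float(t),
        p_one_sided=p_one, p_two_sided=p_two, ci_level=ci_level,
        ci_lower=lo, ci_upper=hi, alternative_direction=direction,
        n_obs=tuple(n_obs), serial=serial,
    )


def paired_serial_level(
    d: PairedDifferenceSeries | Sequence[float],
    ci_level: float = 0.95,
    direction: str = "greater",
    rho: float | None = None,
    _serial: bool = True,
) -> SerialTestResult:
    """Serial t-test for level change on within-pair differences.

    ``rho`` overrides the estimated serial correlation (``rho=0``
    reproduces the usual one-sample t-test exactly).
    """
    y = _as_values(d)
    m = y.size
    if m < 4:
        raise ValueError(f"paired level test requires m >= 4, got m={m}")
    estimate = float(y.mean())
    e = level_residuals(y)
    s2 = float(e @ e) / (m - 1)
    if s2 <= 0:
        raise ZeroVarianceError("zero residual variance in differences")
    corr = None
    if rho is None:
        corr = fuller_r(rho_hat_mle(e), m)
        r = corr.r
    else:
        r = rho
    kern = ar1_kernel(m, r, ChangeType.LEVEL)
    df = kern.m_prime - 1
    _check_df(df)
    return _build_result(Design.PAIRED_LEVEL, estimate, s2, corr, r, [kern], df,
                         ci_level, direction, (m,), _serial)


def paired_serial_rate(
    d: PairedDifferenceSeries | Sequence[float],
    ci_level: float = 0.95,
    direction: str = "greater",
    rho: float | None = None,
    _serial: bool = True,
) -> SerialTestResult:
    """Serial t-test for rate change (slope of differences on time)."""
    y = _as_values(d)
    m = y.size
    if m < 5:
        raise ValueError(f"paired rate test requires m >= 5, got m={m}")
    x = centered_index(m)
    slope = float(x @ y) / float(x @ x)
    e = rate_residuals(y)
    s2 = float(e @ e) / (m - 2)
    if s2 <= 0:
        raise ZeroVarianceError("zero residual variance after detrending")
    corr = None
    if rho is None:
        corr = fuller_r(rho_hat_mle(e), m)
        r = corr.r
    else:
        r = rho
    kern = ar1_kernel(m, r, ChangeType.RATE)
    df = kern.m_prime - 2
    _check_df(df)
    return _build_result(Design.PAIRED_RATE, slope, s2, corr, r, [kern], df,
                         ci_level, direction, (m,), _serial)


def _two_sample_prep(a, b, rate: bool, min_each: int, min_total: int):
    ya, yb = _as_values(a), _as_values(b)
    m_a, m_b = ya.size, yb.size
    if m_a < min_each or m_b < min_each:
        raise ValueError(
            f"each arm needs at least {min_each} observations "
            f"(got m_A={m_a}, m_B={m_b})"
        )
    if m_a + m_b < min_total:
        raise ValueError(
            f"total observations must satisfy m_A + m_B >= {min_total} "
            f"(got {m_a + m_b})"
        )
    resid = rate_residuals if rate else level_residuals
    ea, eb = resid(ya), resid(yb)
    return ya, yb, ea, eb, m_a, m_b


def two_sample_serial_level(
    a: ObservationSeries | Sequence[float],
    b: ObservationSeries | Sequence[float],
    ci_level: float = 0.95,
    direction: str = "greater",
    rho: float | None = None,
    _serial: bool = True,
) -> SerialTestResult:
    """Serial t-test for level change between two independent series."""
    ya, yb, ea, eb, m_a, m_b = _two_sample_prep(a, b, False, 3, 7)
    estimate = float(ya.mean() - yb.mean())
    s2 = (float(ea @ ea) + float(eb @ eb)) / (m_a + m_b - 2)
    if s2 <= 0:
        raise ZeroVarianceError("zero pooled variance")
    corr = None
    if rho is None:
        ra = fuller_r(rho_hat_mle(ea), m_a)
        rb = fuller_r(rho_hat_mle(eb), m_b)
        r = pooled_r(ra.r, m_a, rb.r, m_b)
        corr = CorrelationEstimate(
            rho_hat=pooled_r(ra.rho_hat, m_a, rb.rho_hat, m_b),
            r=r, m=m_a + m_b, clamped=ra.clamped or rb.clamped,
        )
    else:
        r = rho
    ka = ar1_kernel(m_a, r, ChangeType.LEVEL)
    kb = ar1_kernel(m_b, r, ChangeType.LEVEL)
    df = ka.m_prime + kb.m_prime - 2
    _check_df(df)
    return _build_result(Design.TWO_SAMPLE_LEVEL, estimate, s2, corr, r,
                         [ka, kb], df, ci_level, direction, (m_a, m_b), _serial)


def two_sample_serial_rate(
    a: ObservationSeries | Sequence[float],
    b: ObservationSeries | Sequence[float],
    ci_level: float = 0.95,
    direction: str = "greater",
    rho: float | None = None,
    _serial: bool = True,
) -> SerialTestResult:
    """Serial t-test for a difference in slopes between two independent series."""
    ya, yb, ea, eb, m_a, m_b = _two_sample_prep(a, b, True, 4, 9)
    xa, xb = centered_index(m_a), centered_index(m_b)
    slope_a = float(xa @ ya) / float(xa @ xa)
    slope_b = float(xb @ yb) / float(xb @ xb)
    estimate = slope_a - slope_b
    s2 = (float(ea @ ea) + float(eb @ eb)) / (m_a + m_b - 4)
    if s2 <= 0:
        raise ZeroVarianceError("zero pooled variance after detrending")
    corr = None
    if rho is None:
        ra = fuller_r(rho_hat_mle(ea), m_a)
        rb = fuller_r(rho_hat_mle(eb), m_b)
        r = pooled_r(ra.r, m_a, rb.r, m_b)
        corr = CorrelationEstimate(
            rho_hat=pooled_r(ra.rho_hat, m_a, rb.rho_hat, m_b),
            r=r, m=m_a + m_b, clamped=ra.clamped or rb.clamped,
        )
    else:
        r = rho
    ka = ar1_kernel(m_a, r, ChangeType.RATE)
    kb = ar1_kernel(m_b, r, ChangeType.RATE)
    df = ka.m_prime + kb.m_prime - 4
    _check_df(df)
    return _build_result(Design.TWO_SAMPLE_RATE, estimate, s2, corr, r,
                         [ka, kb], df, ci_level, direction, (m_a, m_b), _serial)


# ---------------------------------------------------------------------------
# Usual analogues: the serial machinery with the correlation forced to zero
# reproduces the classical tests exactly (c(0) and b(0) give the classical
# standard errors, and m' = m gives the integer degrees of freedom).

def usual_paired_level(d, ci_level: float = 0.95, direction: str = "greater") -> SerialTestResult:
    """Classical one-sample t-test on the differences."""
    y = _as_values(d)
    if y.size < 2:
        raise ValueError("one-sample t-test requires m >= 2")
    return _usual_level_1s(y, ci_level, direction)


def _usual_level_1s(y, ci_level, direction):
    m = y.size
    e = level_residuals(y)
    s2 = float(e @ e) / (m - 1)
    if s2 <= 0:
        raise ZeroVarianceError("zero variance")
    kern = ar1_kernel(m, 0.0, ChangeType.LEVEL)
    return _build_result(Design.PAIRED_LEVEL, float(y.mean()), s2, None, None,
                         [kern], m - 1, ci_level, direction, (m,), False)


def usual_two_sample_level(a, b, ci_level: float = 0.95, direction: str = "greater") -> SerialTestResult:
    """Classical pooled two-sample t-test."""
    ya, yb = _as_values(a), _as_values(b)
    m_a, m_b = ya.size, yb.size
    if m_a < 2 or m_b < 2:
        raise ValueError("two-sample t-test requires m >= 2 per arm")
    ea, eb = level_residuals(ya), level_residuals(yb)
    s2 = (float(ea @ ea) + float(eb @ eb)) / (m_a + m_b - 2)
    if s2 <= 0:
        raise ZeroVarianceError("zero pooled variance")
    ka = ar1_kernel(m_a, 0.0, ChangeType.LEVEL)
    kb = ar1_kernel(m_b, 0.0, ChangeType.LEVEL)
    return _build_result(Design.TWO_SAMPLE_LEVEL, float(ya.mean() - yb.mean()),
                         s2, None, None, [ka, kb], m_a + m_b - 2, ci_level,
                         direction, (m_a, m_b), False)


def usual_paired_rate(d, ci_level: float = 0.95, direction: str = "greater") -> SerialTestResult:
    """Classical t-test of the slope in a simple linear regression."""
    y = _as_values(d)
    m = y.size
    if m < 3:
        raise ValueError("slope t-test requires m >= 3")
    x = centered_index(m)
    slope = float(x @ y) / float(x @ x)
    e = rate_residuals(y)
    s2 = float(e @ e) / (m - 2)
    if s2 <= 0:
        raise ZeroVarianceError("zero residual variance")
    kern = ar1_kernel(m, 0.0, ChangeType.RATE)
    return _build_result(Design.PAIRED_RATE, slope, s2, None, None, [kern],
                         m - 2, ci_level, direction, (m,), False)


def usual_two_sample_rate(a, b, ci_level: float = 0.95, direction: str = "greater") -> SerialTestResult:
    """Classical difference-of-slopes t-test with a common residual variance."""
    ya, yb = _as_values(a), _as_values(b)
    m_a, m_b = ya.size, yb.size
    if m_a < 3 or m_b < 3:
        raise ValueError("difference-of-slopes test requires m >= 3 per arm")
    xa, xb = centered_index(m_a), centered_index(m_b)
    slope_a = float(xa @ ya) / float(xa @ xa)
    slope_b = float(xb @ yb) / float(xb @ xb)
    ea, eb = rate_residuals(ya), rate_residuals(yb)
    s2 = (float(ea @ ea) + float(eb @ eb)) / (m_a + m_b - 4)
    if s2 <= 0:
        raise ZeroVarianceError("zero pooled variance")
    ka = ar1_kernel(m_a, 0.0, ChangeType.RATE)
    kb = ar1_kernel(m_b, 0.0, ChangeType.RATE)
    return _build_result(Design.TWO_SAMPLE_RATE, slope_a - slope_b, s2, None,
                         None, [ka, kb], m_a + m_b - 4, ci_level, direction,
                         (m_a, m_b), False)


def screen_change(
    a: ObservationSeries | Sequence[float],
    b: ObservationSeries | Sequence[float],
    alpha: float = 0.05,
    paired: bool = False,
) -> dict:
    """Bonferroni screen for any change: level and rate each tested at alpha/2.

    Returns a dict with the two results and boolean flags; 'changed' is True
    if either two-sided p-value is below alpha/2.
    """
    if paired:
        d = PairedDifferenceSeries.from_arms(ObservationSeries(_as_values(a)),
                                             ObservationSeries(_as_values(b)))
        level = paired_serial_level(d)
        rate = paired_serial_rate(d)
    else:
        level = two_sample_serial_level(a, b)
        rate = two_sample_serial_rate(a, b)
    thr = alpha / 2.0
    return {
        "level": level,
        "rate": rate,
        "level_change": level.p_two_sided < thr,
        "rate_change": rate.p_two_sided < thr,
        "changed": level.p_two_sided < thr or rate.p_two_sided < thr,
    }
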