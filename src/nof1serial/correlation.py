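"""Serial-correlation estimation from OLS residuals.

The lag-1 correlation is estimated from residuals of the fitted location
model. Because the residuals sum to zero, the maximum likelihood estimator
simplifies to a lag-1 product sum over the residual sum of squares. That
estimator is badly biased at the short series lengths typical of N-of-1
trials (bias about ``-2 rho / (m - 1)``), so the bias-corrected estimator

    r = rho_hat + (1 - rho_hat^2) / (m - 1)

(Fuller's estimator) is used throughout. Two-sample designs estimate r per
arm and combine with a length-weighted mean.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .ar1_kernels import RHO_CLAMP

__all__ = [
    "Design",
    "ResidualSeries",
    "CorrelationEstimate",
    "ZeroVarianceError",
    "level_residuals",
    "rate_residuals",
    "rho_hat_mle",
    "fuller_r",
    "pooled_r",
    "estimate_serial_r",
]


class Design(str, Enum):
    """The four supported test designs."""

    PAIRED_LEVEL = "paired_level"
    TWO_SAMPLE_LEVEL = "two_sample_level"
    PAIRED_RATE = "paired_rate"
    TWO_SAMPLE_RATE = "two_sample_rate"

    @property
    def is_paired(self) -> bool:
        return self in (Design.PAIRED_LEVEL, Design.PAIRED_RATE)

    @property
    def is_rate(self) -> bool:
        return self in (Design.PAIRED_RATE, Design.TWO_SAMPLE_RATE)


class ZeroVarianceError(ValueError):
    """All residuals are zero; the test statistic is undefined."""


@dataclass(frozen=True)
class ResidualSeries:
    values: np.ndarray
    design: Design
    m: int


@dataclass(frozen=True)
class CorrelationEstimate:
    """Uncorrected MLE and its bias-corrected version for one series."""

    rho_hat: float
    r: float
    m: int
    clamped: bool


def centered_index(m: int) -> np.ndarray:
    """The rate-change predictor: (1, ..., m) minus its mean."""
    return np.arange(1, m + 1, dtype=float) - (m + 1) / 2.0


def level_residuals(values: np.ndarray) -> np.ndarray:
    """Deviations from the series mean."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("insufficient observations for level residuals")
    return values - values.mean()


def rate_residuals(values: np.ndarray) -> np.ndarray:
    """Residuals from the intercept+slope fit on the centered index."""
    values = np.asarray(values, dtype=float)
    m = values.size
    if m < 3:
        raise ValueError("insufficient observations for rate residuals")
    x = centered_index(m)
    slope = float(x @ values) / float(x @ x)
    return values - values.mean() - slope * x


def rho_hat_mle(e: np.ndarray) -> float:
    """Lag-1 product sum over the full sum of squares of residuals.

    Valid for residuals with zero mean (always true for OLS fits with an
    intercept).
    """
    e = np.asarray(e, dtype=float)
    ss = float(e @ e)
    if ss <= 0.0:
        raise ZeroVarianceError("zero residual variance: serial correlation undefined")
    return float(e[1:] @ e[:-1]) / ss


def fuller_r(rho_hat: float, m: int) -> CorrelationEstimate:
    """Bias-corrected serial correlation, clamped away from +/-1."""
    if m < 3:
        raise ValueError("too few observations for correlation estimation (m < 3)")
    if not abs(rho_hat) <= 1:
        raise ValueError(f"rho_hat={rho_hat} outside [-1, 1]")
    r = rho_hat + (1.0 - rho_hat**2) / (m - 1)
    clamped = abs(r) > RHO_CLAMP
    if clamped:
        r = float(np.clip(r, -RHO_CLAMP, RHO_CLAMP))
    return CorrelationEstimate(rho_hat=rho_hat, r=r, m=m, clamped=clamped)


def pooled_r(r_a: float, m_a: int, r_b: float, m_b: int) -> float:
    """Length-weighted mean of the two per-arm estimates."""
    return (m_a * r_a + m_b * r_b) / (m_a + m_b)


def estimate_serial_r(values: np.ndarray, rate: bool = False) -> CorrelationEstimate:
    """Residuals -> rho_hat -> Fuller r for a single series."""
    values = np.asarray(values, dtype=float)
    e = rate_residuals(values) if rate else level_residuals(values)
    return fuller_r(rho_hat_mle(e), values.size)
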