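"""Closed-form AR(1) variance/bias kernels for level- and rate-change designs.

For a single equally spaced series of ``m`` observations with lag-1
autocorrelation ``rho``, ordinary least squares on the location model has

* ``Var(estimate) = c(rho) * sigma^2``  (variance factor),
* ``E(s^2)        = b(rho) * sigma^2``  (bias factor of the naive variance),

and the information content of the series is summarised by the effective
sample size ``m_prime``, related to ``b`` through
``b = m (m' - p) / (m' (m - p))`` where ``p`` is the number of location
parameters (1 for level change, 2 for rate change).

All production code evaluates the O(1) closed forms; :func:`matrix_oracle`
is a dense matrix-algebra cross-check intended for the test suite only.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

__all__ = [
    "ChangeType",
    "Ar1Kernel",
    "c_level",
    "b_level",
    "m_prime_level",
    "c_rate",
    "b_rate",
    "m_prime_rate",
    "ar1_kernel",
    "matrix_oracle",
    "RHO_CLAMP",
]

#: callers clamp estimated correlations to +/- this value before evaluating
#: kernels; the closed forms are singular at rho = 1.
RHO_CLAMP = 0.999


class ChangeType(str, Enum):
    """Type of treatment difference: shift in level or in linear rate."""

    LEVEL = "level"
    RATE = "rate"

    @property
    def n_location_params(self) -> int:
        """Location parameters estimated per series (p)."""
        return 1 if self is ChangeType.LEVEL else 2


@dataclass(frozen=True)
class Ar1Kernel:
    """The kernel triple (c, b, m') for one series at a given m and rho."""

    m: int
    rho: float
    change_type: ChangeType
    c: float
    b: float
    m_prime: float

    @property
    def p(self) -> int:
        return self.change_type.n_location_params

    @property
    def df(self) -> float:
        """Fractional error degrees of freedom contributed by this series."""
        return self.m_prime - self.p


def _check_domain(m: int, rho: float, m_min: int) -> None:
    if m < m_min:
        raise ValueError(f"series length m={m} below the minimum {m_min}")
    if not abs(rho) < 1:
        raise ValueError(f"rho={rho} outside the open interval (-1, 1)")


def c_level(m: int, rho: float) -> float:
    """Variance factor for the sample mean of an AR(1) series.

    ``Var(ybar) = c_level(m, rho) * sigma^2``; reduces to ``1/m`` at rho=0.
    """
    _check_domain(m, rho, 2)
    if rho == 0.0:
        return 1.0 / m
    return (m + 2 * rho ** (m + 1) - m * rho**2 - 2 * rho) / (m**2 * (rho - 1) ** 2)


def b_level(m: int, rho: float) -> float:
    """Bias factor of the OLS variance estimate in the level-change design."""
    return m * (1.0 - c_level(m, rho)) / (m - 1)


def m_prime_level(m: int, rho: float) -> float:
    """Effective sample size of an AR(1) series under the level-change design."""
    return m / (m - (m - 1) * b_level(m, rho))


def c_rate(m: int, rho: float) -> float:
    """Variance factor for the OLS slope on the centered index.

    The predictor is ``x = (1, ..., m) - (m + 1)/2`` (one unit per time
    step); ``Var(slope) = c_rate(m, rho) * sigma^2``. Reduces to
    ``12 / (m (m^2 - 1))`` at rho=0.
    """
    _check_domain(m, rho, 3)
    if rho == 0.0:
        return 12.0 / (m * (m**2 - 1))
    d = rho - 1.0
    inner = (
        -6 * rho * (rho + 1) ** 2 * (rho**m - 1) / (m**2 * d**4)
        + 2 * rho * (6 * rho ** (m + 1) + 6 * rho**m + rho**2 - 2 * rho + 1) / (m * d**3)
        - 6 * rho * (rho**m + 1) / d**2
        - 2 * m * rho / d
        + (m**2 - 1) / m
    )
    return 12.0 / (m**2 - 1) ** 2 * inner


def b_rate(m: int, rho: float) -> float:
    """Bias factor of the OLS variance estimate in the rate-change design."""
    _check_domain(m, rho, 3)
    if rho == 0.0:
        return 1.0
    d = rho - 1.0
    return (
        m
        - 1
        - 2 * rho * (rho**m - m * rho + m - 1) / (m * d**2)
        - m * (m**2 - 1) * c_rate(m, rho) / 12.0
    ) / (m - 2)


def m_prime_rate(m: int, rho: float) -> float:
    """Effective sample size of an AR(1) series under the rate-change design."""
    return 2 * m / (m - (m - 2) * b_rate(m, rho))


def ar1_kernel(m: int, rho: float, change_type: ChangeType) -> Ar1Kernel:
    """Bundle (c, b, m') for one series."""
    change_type = ChangeType(change_type)
    if change_type is ChangeType.LEVEL:
        c, b, mp = c_level(m, rho), b_level(m, rho), m_prime_level(m, rho)
    else:
        c, b, mp = c_rate(m, rho), b_rate(m, rho), m_prime_rate(m, rho)
    return Ar1Kernel(m=m, rho=rho, change_type=change_type, c=c, b=b, m_prime=mp)


def _design_matrix(m: int, change_type: ChangeType) -> np.ndarray:
    ones = np.ones(m)
    if change_type is ChangeType.LEVEL:
        return ones[:, None]
    x = np.arange(1, m + 1) - (m + 1) / 2.0
    return np.column_stack([ones, x])


def matrix_oracle(m: int, rho: float, change_type: ChangeType) -> tuple[float, float]:
    """Dense matrix-algebra evaluation of (c, b). Test-only cross-check.

    Builds ``R[j, k] = rho**|j - k|`` and the design matrix explicitly,
    then returns the slope-relevant diagonal entry of
    ``(X'X)^-1 X'RX (X'X)^-1`` and ``(m - tr(P_X R)) / (m - p)``.
    """
    change_type = ChangeType(change_type)
    if m > 200:
        raise ValueError("matrix oracle restricted to m <= 200")
    _check_domain(m, rho, change_type.n_location_params + 1)
    idx = np.arange(m)
    R = rho ** np.abs(idx[:, None] - idx[None, :])
    X = _design_matrix(m, change_type)
    xtx_inv = np.linalg.inv(X.T @ X)
    v = xtx_inv @ X.T @ R @ X @ xtx_inv
    c = float(v[-1, -1])  # intercept (level) or slope (rate) entry
    P = X @ xtx_inv @ X.T
    p = change_type.n_location_params
    b = float((m - np.trace(P @ R)) / (m - p))
    return c, b
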