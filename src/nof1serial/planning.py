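"""Study-planning calculators: expected CI margins and detectable effect sizes.

Both calculators take an assumed serial correlation and series length,
evaluate the AR(1) kernels of the chosen design, and work on the fractional
degrees of freedom m' - p.

* Expected margin of error of a (1-alpha)100% CI:
  ``t_{DF, 1-alpha/2} * sqrt(c * sigma^2 / b)`` (summed c/b terms for the
  2-sample designs).
* Detectable effect size at a given power: maps the design onto an
  equivalent one-sample noncentral-t calculator with fractional sample size
  ``m_C = DF + 1``, solves for the calculator's effect size ``delta_C``,
  and scales back via ``delta = delta_C * sqrt(m_C * c)``.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .ar1_kernels import ChangeType, ar1_kernel
from .correlation import Design

__all__ = [
    "PlanningRequest",
    "PlanningResult",
    "expected_margin",
    "detectable_effect_size",
    "noncentral_t_power",
    "planning_table",
    "round_half_away",
]


@dataclass(frozen=True)
class PlanningRequest:
    design: Design
    m: int | None = None
    m_a: int | None = None
    m_b: int | None = None
    rho: float = 0.0
    alpha: float = 0.10
    sided: str = "two"  # tail count for the margin's t-quantile
    power: float = 0.80
    sigma2: float = 1.0

    def arm_sizes(self) -> tuple[int, ...]:
        design = Design(self.design)
        if design.is_paired:
            if self.m is None:
                raise ValueError("paired designs require m")
            return (self.m,)
        m_a = self.m_a if self.m_a is not None else self.m
        m_b = self.m_b if self.m_b is not None else self.m
        if m_a is None or m_b is None:
            raise ValueError("two-sample designs require m (or m_a and m_b)")
        return (m_a, m_b)


@dataclass(frozen=True)
class PlanningResult:
    design: Design
    rho: float
    df: float
    margin: float | None = None
    delta: float | None = None
    m_c: float | None = None
    delta_c: float | None = None


_MIN_M = {
    Design.PAIRED_LEVEL: 4,
    Design.PAIRED_RATE: 5,
    Design.TWO_SAMPLE_LEVEL: 3,
    Design.TWO_SAMPLE_RATE: 4,
}


def _design_kernels(req: PlanningRequest):
    design = Design(req.design)
    sizes = req.arm_sizes()
    m_min = _MIN_M[design]
    for m in sizes:
        if m < m_min:
            raise ValueError(f"{design.value} requires m >= {m_min}, got {m}")
    change = ChangeType.RATE if design.is_rate else ChangeType.LEVEL
    kernels = [ar1_kernel(m, req.rho, change) for m in sizes]
    df = sum(k.m_prime for k in kernels) - change.n_location_params * len(kernels)
    if df <= 0:
        raise ValueError(
            f"design infeasible at rho={req.rho}, m={sizes}: DF={df:.4g} <= 0"
        )
    return design, kernels, df


def expected_margin(req: PlanningRequest) -> PlanningResult:
    """Expected CI half-width in sigma units (times sqrt(sigma2))."""
    design, kernels, df = _design_kernels(req)
    tail = req.alpha / 2.0 if req.sided == "two" else req.alpha
    q = float(stats.t.ppf(1.0 - tail, df))
    se = float(np.sqrt(req.sigma2 * sum(k.c / k.b for k in kernels)))
    return PlanningResult(design=design, rho=req.rho, df=df, margin=q * se)


def noncentral_t_power(delta_c: float, m_c: float, alpha: float, sided: str = "one") -> float:
    """Power of a one-sample t-test with fractional sample size m_c.

    ``delta_c`` is the effect in sigma units; the noncentrality parameter is
    ``delta_c * sqrt(m_c)`` and the degrees of freedom ``m_c - 1``.
    """
    df = m_c - 1.0
    if df <= 0:
        raise ValueError("m_c must exceed 1")
    ncp = delta_c * np.sqrt(m_c)
    if sided == "one":
        crit = stats.t.ppf(1.0 - alpha, df)
        return float(stats.nct.sf(crit, df, ncp))
    crit = stats.t.ppf(1.0 - alpha / 2.0, df)
    return float(stats.nct.sf(crit, df, ncp) + stats.nct.cdf(-crit, df, ncp))


def detectable_effect_size(req: PlanningRequest) -> PlanningResult:
    """Effect size (sigma units) detectable with the requested power.

    Follows the one-sample-calculator mapping: m_C = DF + 1 (fractional),
    solve for delta_C, then delta = delta_C * sqrt(m_C * c) where c is the
    design's total variance factor (c_A + c_B for 2-sample designs).
    """
    design, kernels, df = _design_kernels(req)
    if not 0.0 < req.power < 1.0:
        raise ValueError("power must lie in (0, 1)")
    m_c = df + 1.0
    sided = "one" if req.sided == "one" else "two"

    def gap(delta_c: float) -> float:
        return noncentral_t_power(delta_c, m_c, req.alpha, sided) - req.power

    lo, hi = 1e-8, 1e4
    if gap(hi) < 0:
        raise ValueError("unattainable power for this design")
    delta_c = float(optimize.brentq(gap, lo, hi, xtol=1e-10, rtol=1e-12))
    c_total = sum(k.c for k in kernels)
    delta = delta_c * float(np.sqrt(m_c * c_total))
    return PlanningResult(design=design, rho=req.rho, df=df, delta=delta,
                          m_c=m_c, delta_c=delta_c)


def round_half_away(x: float, decimals: int = 2) -> float:
    """Round half away from zero, matching conventional table display."""
    q = decimal.Decimal(1).scaleb(-decimals)
    return float(decimal.Decimal(repr(float(x))).quantize(q, rounding=decimal.ROUND_HALF_UP))


def planning_table(
    design: Design | str,
    m_range=range(4, 13),
    rho_list=(0.0, 0.2, 0.4, 0.6, 0.8),
    mode: str = "margin",
    alpha: float = 0.10,
    power: float = 0.80,
    sigma2: float = 1.0,
    sided: str = "two",
    decimals: int | None = 2,
) -> pd.DataFrame:
    """Grid of margins or detectable effect sizes (rows rho, columns m).

    For 2-sample designs ``m`` is taken per arm. Infeasible cells are NaN.
    The defaults reproduce the reference planning grids for the paired
    level-change test (90% CI margins; 0.80 power at one-sided alpha 0.05).
    """
    design = Design(design)
    rows = {}
    for rho in rho_list:
        row = []
        for m in m_range:
            req = PlanningRequest(design=design, m=m, rho=rho, alpha=alpha,
                                  sided=sided, power=power, sigma2=sigma2)
            if not design.is_paired:
                req = PlanningRequest(design=design, m_a=m, m_b=m, rho=rho,
                                      alpha=alpha, sided=sided, power=power,
                                      sigma2=sigma2)
            try:
                if mode == "margin":
                    val = expected_margin(req).margin
                elif mode == "delta":
                    val = detectable_effect_size(req).delta
                else:
                    raise ValueError(f"unknown mode {mode!r}")
            except ValueError as exc:
                if "infeasible" in str(exc) or "requires m" in str(exc):
                    val = np.nan
                else:
                    raise
            if decimals is not None and np.isfinite(val):
                val = round_half_away(val, decimals)
            row.append(val)
        rows[rho] = row
    table = pd.DataFrame.from_dict(rows, orient="index", columns=list(m_range))
    table.index.name = "rho"
    table.columns.name = "m"
    return table
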