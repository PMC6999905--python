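"""AR(1) data generation and the Monte Carlo property experiments.

The generator draws stationary AR(1) series: the first deviation at the
full marginal variance, subsequent deviations via
``z_j = rho * z_{j-1} + sqrt(1 - rho^2) * sigma * eps_j``. The paired
generator shares the serial parameter across arms and cross-correlates the
innovations so that the contemporaneous within-pair correlation equals
``rho_pair`` exactly at every time point; the within-pair differences are
then themselves AR(1) with the same serial parameter and variance
``2 sigma^2 (1 - rho_pair)``.

Three experiments summarise statistical properties over replicated trials:
empirical Type I error, the empirically detectable effect size relative to
its theoretical value, and the mean realized CI margin relative to the
theoretical margin at the true correlation. Replicates with degenerate
estimates (zero residual variance or non-positive degrees of freedom) are
excluded from rejection denominators and counted separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .correlation import Design, ZeroVarianceError, centered_index
from .planning import PlanningRequest, detectable_effect_size, expected_margin
from .serial_tests import (
    DegreesOfFreedomError,
    SerialTestResult,
    paired_serial_level,
    paired_serial_rate,
    two_sample_serial_level,
    two_sample_serial_rate,
    usual_paired_level,
    usual_paired_rate,
    usual_two_sample_level,
    usual_two_sample_rate,
)

__all__ = [
    "SimulationConfig",
    "SimulationSummary",
    "generate_ar1",
    "generate_paired_ar1",
    "run_type1_experiment",
    "run_delta_ratio_experiment",
    "run_margin_factor_experiment",
]

_SERIAL = {
    Design.PAIRED_LEVEL: paired_serial_level,
    Design.PAIRED_RATE: paired_serial_rate,
    Design.TWO_SAMPLE_LEVEL: two_sample_serial_level,
    Design.TWO_SAMPLE_RATE: two_sample_serial_rate,
}
_USUAL = {
    Design.PAIRED_LEVEL: usual_paired_level,
    Design.PAIRED_RATE: usual_paired_rate,
    Design.TWO_SAMPLE_LEVEL: usual_two_sample_level,
    Design.TWO_SAMPLE_RATE: usual_two_sample_rate,
}


@dataclass(frozen=True)
class SimulationConfig:
    design: Design
    m: int
    rho: float
    rho_pair: float = 0.0
    sigma2: float = 1.0
    mu: float = 0.0
    beta: float = 0.0
    n_reps: int = 10_000
    alpha: float = 0.05
    sided: str = "one"
    seed: int = 0

    def __post_init__(self) -> None:
        design = Design(self.design)
        object.__setattr__(self, "design", design)
        if not design.is_paired and self.rho_pair != 0.0:
            raise ValueError("two-sample designs require rho_pair = 0")
        if not 0.0 <= self.rho_pair < 1.0:
            raise ValueError("rho_pair must lie in [0, 1)")


@dataclass(frozen=True)
class SimulationSummary:
    config: SimulationConfig
    n_reps: int
    n_excluded: int = 0
    type1_serial: float | None = None
    type1_usual: float | None = None
    power_serial: float | None = None
    power_usual: float | None = None
    mc_halfwidth: float | None = None
    theoretical_delta: float | None = None
    delta_hat: float | None = None
    delta_ratio: float | None = None
    theoretical_margin: float | None = None
    mean_margin_serial: float | None = None
    mean_margin_usual: float | None = None
    margin_factor_serial: float | None = None
    margin_factor_usual: float | None = None
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "design": self.config.design.value,
            "m": self.config.m,
            "rho": self.config.rho,
            "rho_pair": self.config.rho_pair,
            "seed": self.config.seed,
            "alpha": self.config.alpha,
            "n_reps": self.n_reps,
            "n_excluded": self.n_excluded,
        }
        for k in ("type1_serial", "type1_usual", "power_serial", "power_usual",
                  "mc_halfwidth", "theoretical_delta", "delta_hat",
                  "delta_ratio", "theoretical_margin", "mean_margin_serial",
                  "mean_margin_usual", "margin_factor_serial",
                  "margin_factor_usual"):
            v = getattr(self, k)
            if v is not None:
                d[k] = v
        return d


def generate_ar1(m, rho, sigma2=1.0, mean=0.0, rng=None, size=None):
    """Stationary AR(1) series with the given mean vector.

    ``mean`` may be a scalar or length-m vector. With ``size=n`` an
    ``(n, m)`` array of independent series is returned.
    """
    if not abs(rho) < 1:
        raise ValueError(f"rho={rho} outside (-1, 1)")
    rng = np.random.default_rng(rng)
    n = 1 if size is None else size
    sigma = np.sqrt(sigma2)
    z = np.empty((n, m))
    eps = rng.standard_normal((n, m))
    z[:, 0] = sigma * eps[:, 0]
    innov_sd = sigma * np.sqrt(1.0 - rho**2)
    for j in range(1, m):
        z[:, j] = rho * z[:, j - 1] + innov_sd * eps[:, j]
    out = z + np.asarray(mean, dtype=float)
    return out[0] if size is None else out


def generate_paired_ar1(m, rho, rho_pair, sigma2=1.0, mean_a=0.0, mean_b=0.0,
                        rng=None, size=None):
    """Two stationary AR(1) arms with cross-correlated innovations.

    Both arms share the serial parameter ``rho``; innovations (and the
    initial deviations) are jointly Gaussian with correlation ``rho_pair``,
    which makes ``Corr(A_j, B_j) = rho_pair`` for every j.
    """
    if not abs(rho) < 1:
        raise ValueError(f"rho={rho} outside (-1, 1)")
    if not 0.0 <= rho_pair < 1.0:
        raise ValueError("rho_pair must lie in [0, 1)")
    rng = np.random.default_rng(rng)
    n = 1 if size is None else size
    sigma = np.sqrt(sigma2)
    # cross-correlated standard normal pairs
    e1 = rng.standard_normal((n, m))
    e2 = rng.standard_normal((n, m))
    f2 = rho_pair * e1 + np.sqrt(1.0 - rho_pair**2) * e2
    za = np.empty((n, m))
    zb = np.empty((n, m))
    za[:, 0] = sigma * e1[:, 0]
    zb[:, 0] = sigma * f2[:, 0]
    innov_sd = sigma * np.sqrt(1.0 - rho**2)
    for j in range(1, m):
        za[:, j] = rho * za[:, j - 1] + innov_sd * e1[:, j]
        zb[:, j] = rho * zb[:, j - 1] + innov_sd * f2[:, j]
    a = za + np.asarray(mean_a, dtype=float)
    b = zb + np.asarray(mean_b, dtype=float)
    if size is None:
        return a[0], b[0]
    return a, b


def _null_means(config: SimulationConfig):
    x = centered_index(config.m)
    mean = config.mu + config.beta * x
    return mean, mean


def _draw_all(config: SimulationConfig, rng, mean_a, mean_b, n: int):
    """All replicates at once; yields per-rep argument tuples."""
    if config.design.is_paired:
        if config.rho_pair == 0.0:
            # simulate the within-pair difference series directly; sigma2 is
            # then the variance of the differences
            d = generate_ar1(config.m, config.rho, config.sigma2,
                             np.asarray(mean_a) - np.asarray(mean_b), rng, size=n)
            return [(d[i],) for i in range(n)]
        a, b = generate_paired_ar1(config.m, config.rho, config.rho_pair,
                                   config.sigma2, mean_a, mean_b, rng, size=n)
        d = a - b
        return [(d[i],) for i in range(n)]
    a = generate_ar1(config.m, config.rho, config.sigma2, mean_a, rng, size=n)
    b = generate_ar1(config.m, config.rho, config.sigma2, mean_b, rng, size=n)
    return [(a[i], b[i]) for i in range(n)]


def _run_tests(config, data):
    """One replicate: (serial result | None, usual result | None)."""
    try:
        serial = _SERIAL[config.design](*data, direction="greater")
    except (ZeroVarianceError, DegreesOfFreedomError):
        serial = None
    try:
        usual = _USUAL[config.design](*data, direction="greater")
    except ZeroVarianceError:
        usual = None
    return serial, usual


def _rejects(result: SerialTestResult, alpha: float, sided: str) -> bool:
    p = result.p_one_sided if sided == "one" else result.p_two_sided
    return p < alpha


def _halfwidth(p: float, n: int) -> float:
    return 1.96 * np.sqrt(max(p * (1 - p), 1e-12) / n)


def run_type1_experiment(config: SimulationConfig,
                         effect: float = 0.0) -> SimulationSummary:
    """Empirical rejection rate under the null (or at a mean shift ``effect``).

    ``effect`` shifts the level (level designs) or slope (rate designs) of
    arm A, in response units; 0 gives the Type I error rate.
    """
    rng = np.random.default_rng(config.seed)
    mean_a, mean_b = _null_means(config)
    if effect != 0.0:
        if config.design.is_rate:
            mean_a = mean_a + effect * centered_index(config.m)
        else:
            mean_a = mean_a + effect
    rej_s = rej_u = 0
    n_s = n_u = 0
    excluded = 0
    for data in _draw_all(config, rng, mean_a, mean_b, config.n_reps):
        serial, usual = _run_tests(config, data)
        if serial is None:
            excluded += 1
        else:
            n_s += 1
            rej_s += _rejects(serial, config.alpha, config.sided)
        if usual is not None:
            n_u += 1
            rej_u += _rejects(usual, config.alpha, config.sided)
    rate_s = rej_s / n_s if n_s else np.nan
    rate_u = rej_u / n_u if n_u else np.nan
    kwargs = dict(config=config, n_reps=config.n_reps, n_excluded=excluded,
                  mc_halfwidth=_halfwidth(rate_s, max(n_s, 1)))
    if effect == 0.0:
        return SimulationSummary(type1_serial=rate_s, type1_usual=rate_u, **kwargs)
    return SimulationSummary(power_serial=rate_s, power_usual=rate_u, **kwargs)


def empirical_power(config: SimulationConfig, effect: float,
                    use_usual: bool = False) -> float:
    """Serial (or usual) test power at a given effect, by simulation."""
    summary = run_type1_experiment(config, effect=effect)
    return summary.power_usual if use_usual else summary.power_serial


def _theoretical_delta(config: SimulationConfig) -> float:
    design = config.design
    req = PlanningRequest(design=design, m=config.m, m_a=config.m,
                          m_b=config.m, rho=config.rho, alpha=config.alpha,
                          sided=config.sided, power=0.80,
                          sigma2=1.0)
    return detectable_effect_size(req).delta


def run_delta_ratio_experiment(config: SimulationConfig, power: float = 0.80,
                               use_usual: bool = False,
                               n_iter: int = 14) -> SimulationSummary:
    """Bisection on the effect axis for the empirically detectable effect.

    Finds the effect (sigma units) at which the simulated power reaches the
    target, then reports its ratio to the theoretical effect size from the
    planning calculator at the true correlation.
    """
    theo = _theoretical_delta(config)
    sigma = np.sqrt(config.sigma2)
    lo, hi = 0.0, 4.0 * max(theo, 1.0)
    while empirical_power(replace(config, seed=config.seed + 1),
                          hi * sigma, use_usual) < power:
        hi *= 2.0
        if hi > 1e6:
            raise RuntimeError("power target unreachable in bisection")
    for i in range(n_iter):
        mid = 0.5 * (lo + hi)
        p = empirical_power(replace(config, seed=config.seed + 2 + i),
                            mid * sigma, use_usual)
        if p < power:
            lo = mid
        else:
            hi = mid
    delta_hat = 0.5 * (lo + hi)
    return SimulationSummary(
        config=config, n_reps=config.n_reps,
        power_serial=None if use_usual else power,
        power_usual=power if use_usual else None,
        theoretical_delta=theo, delta_hat=delta_hat,
        delta_ratio=delta_hat / theo,
    )


def run_margin_factor_experiment(config: SimulationConfig,
                                 ci_level: float = 0.90) -> SimulationSummary:
    """Mean estimated expected margin relative to the theoretical margin.

    Each replicate plugs its estimates into the expected-margin formula:
    the serial margin uses the estimated correlation's kernels, fractional
    degrees of freedom and the bias-corrected variance estimate
    ``s_tilde^2 = s^2 / b(r)``; the usual margin keeps the classical
    quantile and standard-error structure but the same bias-corrected
    variance. Both are averaged over replicates and divided by the plug-in
    margin at the true correlation with unit variance.
    """
    alpha = 1.0 - ci_level
    req = PlanningRequest(design=config.design, m=config.m, m_a=config.m,
                          m_b=config.m, rho=config.rho, alpha=alpha,
                          sided="two", sigma2=config.sigma2)
    theo = expected_margin(req).margin
    rng = np.random.default_rng(config.seed)
    mean_a, mean_b = _null_means(config)
    margins_s = []
    margins_u = []
    excluded = 0
    q_usual_cache: dict[float, float] = {}
    for data in _draw_all(config, rng, mean_a, mean_b, config.n_reps):
        serial, usual = _run_tests(config, data)
        if serial is None or usual is None:
            excluded += 1
            continue
        b_hat = np.prod([k.b for k in serial.kernels]) ** (1.0 / len(serial.kernels))
        s2_tilde = serial.s2 / b_hat
        q_s = stats.t.ppf(1.0 - alpha / 2.0, serial.df)
        se_s = np.sqrt(s2_tilde * sum(k.c / k.b for k in serial.kernels))
        margins_s.append(q_s * se_s)
        if usual.df not in q_usual_cache:
            q_usual_cache[usual.df] = stats.t.ppf(1.0 - alpha / 2.0, usual.df)
        se_u = np.sqrt(s2_tilde * sum(k.c for k in usual.kernels))
        margins_u.append(q_usual_cache[usual.df] * se_u)
    mean_s = float(np.mean(margins_s))
    mean_u = float(np.mean(margins_u))
    return SimulationSummary(
        config=config, n_reps=config.n_reps, n_excluded=excluded,
        theoretical_margin=theo, mean_margin_serial=mean_s,
        mean_margin_usual=mean_u,
        margin_factor_serial=mean_s / theo,
        margin_factor_usual=mean_u / theo,
    )
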