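"""Power and sample-size calculations for correlation and two-group designs.

Reimplements the two classical calculations used to size studies of distal
causes: the Fisher-z approximation to the power of a Pearson correlation
test (the ``pwr.r.test`` algorithm) and the noncentral-t power of an
equal-groups two-sample t-test (the ``pwr.t.test`` algorithm).  Solvers
invert these power functions for the continuous sample size achieving a
target power, then apply a documented rounding rule to report an integer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .errors import ChainValidationError

__all__ = [
    "PowerSpec",
    "SampleSizeResult",
    "correlation_power",
    "required_n_correlation",
    "two_sample_t_power",
    "required_total_n_t",
]

_POWER_TOL = 1e-8
_N_XTOL = 1e-10


@dataclass(frozen=True)
class PowerSpec:
    """Significance level, target power and test family for a calculation."""

    alpha: float = 0.05
    target_power: float = 0.80
    sides: int = 2
    test_kind: str = "correlation"

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ChainValidationError("alpha must be in (0, 1)")
        if not 0.0 < self.target_power < 1.0:
            raise ChainValidationError("target power must be in (0, 1)")
        if self.sides not in (1, 2):
            raise ChainValidationError("sides must be 1 or 2")
        if self.test_kind not in ("correlation", "two_sample_t"):
            raise ChainValidationError("test_kind must be 'correlation' or 'two_sample_t'")


@dataclass(frozen=True)
class SampleSizeResult:
    """A solved sample size: the real-valued root and its reported integer.

    ``continuous_solution`` satisfies power = target to within 1e-8 and is
    reported alongside ``reported_n`` so users preferring a different
    rounding convention (e.g. ceiling) can apply their own.
    """

    continuous_solution: float
    reported_n: int
    achieved_power: float
    rounding_rule: str


def correlation_power(
    r: float,
    n: float,
    alpha: float = 0.05,
    sides: int = 2,
) -> float:
    """Power of a Pearson correlation test via bias-corrected Fisher z.

    Follows the ``pwr.r.test`` algorithm: the critical correlation is the
    value rejected exactly at ``alpha`` by the central-t test with
    ``n - 2`` degrees of freedom; both it and the true correlation are
    mapped through the bias-corrected Fisher transform
    ``atanh(r) + r / (2 (n - 1))`` and compared on the approximate normal
    scale with standard error ``1 / sqrt(n - 3)``.
    """
    r = abs(float(r))
    if not 0.0 < r < 1.0:
        raise ChainValidationError("correlation magnitude must be in (0, 1)")
    if n <= 3:
        raise ChainValidationError("need n > 3 for the Fisher-z approximation")
    t_crit = stats.t.isf(alpha / sides, n - 2)
    r_crit = math.sqrt(t_crit**2 / (t_crit**2 + n - 2))
    z_r = math.atanh(r) + r / (2.0 * (n - 1.0))
    z_rc = math.atanh(r_crit) + r_crit / (2.0 * (n - 1.0))
    return float(stats.norm.cdf((z_r - z_rc) * math.sqrt(n - 3.0)))


def two_sample_t_power(
    d: float,
    n_per_group: float,
    alpha: float = 0.05,
    sides: int = 2,
) -> float:
    """Power of an equal-groups two-sample t-test via the noncentral t.

    With ``n`` per group the statistic has ``2n - 2`` degrees of freedom
    and noncentrality ``d * sqrt(n / 2)``; two-sided power adds the mass
    beyond both central-t critical values.
    """
    d = abs(float(d))
    if d <= 0:
        raise ChainValidationError("effect magnitude must be positive")
    if n_per_group <= 1:
        raise ChainValidationError("need more than one participant per group")
    df = 2.0 * n_per_group - 2.0
    ncp = d * math.sqrt(n_per_group / 2.0)
    t_crit = stats.t.isf(alpha / sides, df)
    power = stats.nct.sf(t_crit, df, ncp)
    if sides == 2:
        power = power + stats.nct.cdf(-t_crit, df, ncp)
    return float(power)


def _bracket_root(f, guess: float, lower: float) -> tuple[float, float]:
    """Expand geometrically from a closed-form guess to bracket the root.

    The power functions can be numerically indeterminate at near-zero
    degrees of freedom, so a NaN at the lower end moves the bracket up.
    """
    lo = max(lower, guess / 4.0)
    val = f(lo)
    while math.isfinite(val) and val > 0 and lo > lower * (1 + 1e-12):
        lo = max(lower, lo / 4.0)
        val = f(lo)
    for _ in range(200):
        if math.isfinite(val) and val < 0:
            break
        lo *= 1.5
        val = f(lo)
    else:
        raise ChainValidationError("could not bracket the sample-size root")
    hi = max(guess * 2.0, lo * 2.0)
    for _ in range(200):
        if math.isfinite(f(hi)) and f(hi) >= 0:
            break
        hi *= 2.0
    else:
        raise ChainValidationError("could not bracket the sample-size root")
    return lo, hi


def required_n_correlation(r: float, spec: PowerSpec | None = None) -> SampleSizeResult:
    """Sample size for a correlation test at the target power.

    Solves ``correlation_power(r, n) = target`` for continuous ``n`` and
    reports the floor of the solution.
    """
    spec = spec or PowerSpec()
    r = abs(float(r))
    if not 0.0 < r < 1.0:
        raise ChainValidationError("correlation magnitude must be in (0, 1)")

    def gap(n: float) -> float:
        return correlation_power(r, n, spec.alpha, spec.sides) - spec.target_power

    z_a = stats.norm.isf(spec.alpha / spec.sides)
    z_b = stats.norm.isf(1.0 - spec.target_power)
    guess = ((z_a + z_b) / math.atanh(r)) ** 2 + 3.0
    lo, hi = _bracket_root(gap, guess, lower=4.0 + 1e-9)
    n_star = float(optimize.brentq(gap, lo, hi, xtol=_N_XTOL))
    achieved = correlation_power(r, n_star, spec.alpha, spec.sides)
    if abs(achieved - spec.target_power) > _POWER_TOL:
        raise ChainValidationError("sample-size root did not converge in power")
    return SampleSizeResult(
        continuous_solution=n_star,
        reported_n=int(math.floor(n_star)),
        achieved_power=achieved,
        rounding_rule="floor(continuous n)",
    )


def required_total_n_t(d: float, spec: PowerSpec | None = None) -> SampleSizeResult:
    """Total sample size for an equal-groups two-sample t-test.

    Solves the noncentral-t power equation for the continuous per-group
    size and reports twice that, rounded to the nearest integer (half away
    from zero).
    """
    spec = spec or PowerSpec()
    d = abs(float(d))
    if d <= 0:
        raise ChainValidationError("effect magnitude must be positive")

    def gap(n: float) -> float:
        return two_sample_t_power(d, n, spec.alpha, spec.sides) - spec.target_power

    z_a = stats.norm.isf(spec.alpha / spec.sides)
    z_b = stats.norm.isf(1.0 - spec.target_power)
    guess = max(2.0, 2.0 * ((z_a + z_b) / d) ** 2)
    lo, hi = _bracket_root(gap, guess, lower=1.0 + 1e-6)
    n_star = float(optimize.brentq(gap, lo, hi, xtol=_N_XTOL))
    achieved = two_sample_t_power(d, n_star, spec.alpha, spec.sides)
    if abs(achieved - spec.target_power) > _POWER_TOL:
        raise ChainValidationError("sample-size root did not converge in power")
    total = 2.0 * n_star
    reported = int(math.floor(total + 0.5))
    return SampleSizeResult(
        continuous_solution=n_star,
        reported_n=reported,
        achieved_power=achieved,
        rounding_rule="round(2 * continuous per-group n)",
    )
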