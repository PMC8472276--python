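"""Closed-form expectations for the chain model.

These are the analytic companions to the Monte-Carlo experiments: the
population correlation between the most distal skill and reading ability,
and the expected standardized group difference when a low-reading group is
split off at a z-score cutoff.  Every simulation output in the package can
be checked against these without further simulation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

from .chain import RAW_WEIGHTS, STANDARDIZED_INPUT
from .errors import ChainValidationError

__all__ = [
    "ChainMoments",
    "chain_moments",
    "analytic_correlation",
    "truncated_normal_means",
    "analytic_group_d",
]


@dataclass(frozen=True)
class ChainMoments:
    """Variance recursion of a raw-weight chain with constant link strength.

    ``variance_sequence[L]`` is Var(Skill L) with ``V_0 = 1`` and
    ``V_L = x**2 * V_{L-1} + y**2``; ``covariance_with_a = x**m`` is
    Cov(Skill A, reading); their ratio gives the population correlation.
    """

    variance_sequence: tuple[float, ...]
    covariance_with_a: float
    population_correlation: float


def _validate_xk(x: float, n_intermediate_links: int) -> int:
    if not 0.0 <= x <= 1.0:
        raise ChainValidationError(f"link strength {x!r} outside [0, 1]")
    k = int(n_intermediate_links)
    if k < 0:
        raise ChainValidationError("number of intermediate links must be >= 0")
    return k


def chain_moments(x: float, n_intermediate_links: int) -> ChainMoments:
    """Moments of the raw-weight chain with ``m = k + 1`` steps."""
    k = _validate_xk(x, n_intermediate_links)
    m = k + 1
    y = 1.0 - x
    variances = [1.0]
    for _ in range(m):
        variances.append(x * x * variances[-1] + y * y)
    cov = x**m
    v_m = variances[-1]
    rho = 1.0 if v_m == 0 else cov / math.sqrt(v_m)
    return ChainMoments(tuple(variances), cov, rho)


def analytic_correlation(
    x: float,
    n_intermediate_links: int,
    variant: str = RAW_WEIGHTS,
) -> float:
    """Population correlation between Skill A and reading ability.

    For ``raw_weights`` propagation the correlation is
    ``x**m / sqrt(V_m)`` with the variance recursion
    ``V_L = x**2 * V_{L-1} + y**2``; for ``standardized_input`` every step
    contributes ``x / sqrt(x**2 + y**2)`` and the chain correlation is that
    per-step value to the ``m``-th power.  The variants agree at ``k = 0``.
    """
    k = _validate_xk(x, n_intermediate_links)
    m = k + 1
    y = 1.0 - x
    if variant == RAW_WEIGHTS:
        return chain_moments(x, k).population_correlation
    if variant == STANDARDIZED_INPUT:
        denom = math.hypot(x, y)
        if denom == 0:
            raise ChainValidationError("x and y cannot both be zero")
        return (x / denom) ** m
    raise ChainValidationError(f"unknown propagation variant {variant!r}")


def truncated_normal_means(cutoff: float) -> tuple[float, float]:
    """Conditional means of a standard normal on each side of ``cutoff``.

    Returns ``(E[Z | Z < c], E[Z | Z >= c])``, i.e. the inverse-Mills
    expressions ``-phi(c)/Phi(c)`` and ``phi(c)/(1 - Phi(c))``.
    """
    c = float(cutoff)
    if not math.isfinite(c):
        raise ChainValidationError("cutoff must be finite")
    phi = stats.norm.pdf(c)
    below = stats.norm.cdf(c)
    return (-phi / below, phi / (1.0 - below))


def analytic_group_d(rho: float, cutoff: float = -2.0) -> float:
    """Expected standardized group difference on the distal skill.

    With (Skill A, reading) bivariate normal at correlation ``rho``, the
    mean of Skill A conditional on reading z being below (above) the
    cutoff is ``rho`` times the corresponding truncated-normal mean, so

        d = rho * (E[Z | Z < c] - E[Z | Z >= c])

    which is negative for ``rho > 0`` with a low-tail cutoff.  The full
    population sd of Skill A (the d denominator) is 1.
    """
    if abs(rho) > 1.0:
        raise ChainValidationError("correlation magnitude cannot exceed 1")
    mean_below, mean_above = truncated_normal_means(cutoff)
    return rho * (mean_below - mean_above)
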