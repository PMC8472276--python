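"""Full reproduction of the correlation and group-difference scenario tables.

A scenario grid crosses link strength (low 0.2, medium 0.5, high 0.8) with
the number of intermediate links (4 down to 0).  For each scenario the
correlation table runs the correlation study (1,000 participants,
10,000 replications, raw-weight propagation by default) and sizes a
correlation study on the 3-decimal point estimate; the group table runs
the case-control study (10,000 participants, 10,000 replications,
standardized-input propagation, cutoff z < -2) and sizes a two-sample
t-test on the absolute 3-decimal effect estimate.  Output rows carry the
analytic expectation and Monte-Carlo standard error as provenance.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .chain import RAW_WEIGHTS, STANDARDIZED_INPUT, ChainSpec, MonteCarloDesign
from .experiments import run_correlation_study, run_group_study
from .oracles import analytic_correlation, analytic_group_d
from .power import required_n_correlation, required_total_n_t

logger = logging.getLogger(__name__)

__all__ = [
    "STRENGTH_LEVELS",
    "LINK_COUNTS",
    "ScenarioGrid",
    "build_table1",
    "build_table2",
    "format_table",
]

STRENGTH_LEVELS: tuple[tuple[str, float], ...] = (
    ("Low", 0.2),
    ("Medium", 0.5),
    ("High", 0.8),
)
LINK_COUNTS: tuple[int, ...] = (4, 3, 2, 1, 0)


@dataclass(frozen=True)
class ScenarioGrid:
    """The 15-scenario grid in printed row order (strength, links descending)."""

    strengths: tuple[tuple[str, float], ...] = STRENGTH_LEVELS
    link_counts: tuple[int, ...] = LINK_COUNTS

    def rows(self):
        for label, x in self.strengths:
            for k in self.link_counts:
                yield label, x, k


def round3(value: float) -> float:
    """Round to 3 decimals, half away from zero (table convention)."""
    return float(Decimal(repr(float(value))).quantize(Decimal("0.001"), rounding=ROUND_HALF_UP))


def _scenario_seed(master_seed: int, table_id: int, index: int) -> int:
    """Deterministic per-scenario seed, independent of execution order."""
    ss = np.random.SeedSequence([int(master_seed), table_id, index])
    return int(ss.generate_state(1, np.uint32)[0])


def build_table1(
    seed: int = 0,
    n_participants: int = 1_000,
    n_replications: int = 10_000,
    variant: str = RAW_WEIGHTS,
    grid: ScenarioGrid | None = None,
) -> pd.DataFrame:
    """Correlation between the distal skill and reading, per scenario.

    Returns one row per scenario with the simulated point estimate,
    empirical 95% CI, required sample size for 80% power (computed from
    the 3-decimal estimate), and provenance columns.
    """
    grid = grid or ScenarioGrid()
    t0 = time.perf_counter()
    records = []
    for index, (label, x, k) in enumerate(grid.rows()):
        spec = ChainSpec.constant(x, k, variant)
        design = MonteCarloDesign(
            n_participants=n_participants,
            n_replications=n_replications,
            rng_seed=_scenario_seed(seed, 1, index),
        )
        summary = run_correlation_study(spec, design)
        estimate_3dp = round3(summary.point_estimate)
        rho = analytic_correlation(x, k, variant)
        required = required_n_correlation(estimate_3dp) if 0 < abs(estimate_3dp) < 1 else None
        records.append(
            {
                "relationship_strength": label,
                "link_strength": x,
                "n_intermediate_links": k,
                "correlation_estimate": summary.point_estimate,
                "ci_lower": summary.ci_lower,
                "ci_upper": summary.ci_upper,
                "required_n_80_power": required.reported_n if required else np.nan,
                "required_n_continuous": required.continuous_solution if required else np.nan,
                "analytic_correlation": rho,
                "abs_gap": abs(summary.point_estimate - rho),
                "mc_standard_error": summary.mc_standard_error,
                "seed": seed,
                "n_participants": n_participants,
                "n_replications": n_replications,
                "variant": variant,
            }
        )
    logger.info(
        "correlation table: %d scenarios, %d reps x %d participants, %.1f s",
        len(records), n_replications, n_participants, time.perf_counter() - t0,
    )
    return pd.DataFrame.from_records(records)


def build_table2(
    seed: int = 0,
    n_participants: int = 10_000,
    n_replications: int = 10_000,
    variant: str = STANDARDIZED_INPUT,
    cutoff: float = -2.0,
    grid: ScenarioGrid | None = None,
) -> pd.DataFrame:
    """Standardized dyslexia-vs-control difference on the distal skill.

    Same grid as the correlation table; the required sample size is the
    total across both groups for an equal-groups t-test at 80% power,
    computed from the absolute 3-decimal effect estimate.
    """
    grid = grid or ScenarioGrid()
    t0 = time.perf_counter()
    records = []
    for index, (label, x, k) in enumerate(grid.rows()):
        spec = ChainSpec.constant(x, k, variant)
        design = MonteCarloDesign(
            n_participants=n_participants,
            n_replications=n_replications,
            rng_seed=_scenario_seed(seed, 2, index),
        )
        summary = run_group_study(spec, design, cutoff)
        estimate_3dp = round3(summary.d_estimate)
        expected_d = analytic_group_d(analytic_correlation(x, k, variant), cutoff)
        required = required_total_n_t(abs(estimate_3dp)) if estimate_3dp != 0 else None
        records.append(
            {
                "relationship_strength": label,
                "link_strength": x,
                "n_intermediate_links": k,
                "effect_size_estimate": summary.d_estimate,
                "ci_lower": summary.ci_lower,
                "ci_upper": summary.ci_upper,
                "required_total_n_80_power": required.reported_n if required else np.nan,
                "required_n_per_group_continuous": (
                    required.continuous_solution if required else np.nan
                ),
                "analytic_d": expected_d,
                "abs_gap": abs(summary.d_estimate - expected_d),
                "mc_standard_error": summary.mc_standard_error,
                "mean_n_dyslexia": summary.mean_group_sizes[0],
                "n_excluded_replications": summary.n_excluded_replications,
                "cutoff": cutoff,
                "seed": seed,
                "n_participants": n_participants,
                "n_replications": n_replications,
                "variant": variant,
            }
        )
    logger.info(
        "group table: %d scenarios, %d reps x %d participants, %.1f s",
        len(records), n_replications, n_participants, time.perf_counter() - t0,
    )
    return pd.DataFrame.from_records(records)


def format_table(table: pd.DataFrame, kind: str = "auto") -> pd.DataFrame:
    """Printed-style view: 3-decimal strings and thousands-separated N.

    ``kind`` is "correlation", "group", or "auto" (inferred from columns).
    """
    if kind == "auto":
        kind = "correlation" if "correlation_estimate" in table.columns else "group"
    est_col = "correlation_estimate" if kind == "correlation" else "effect_size_estimate"
    n_col = "required_n_80_power" if kind == "correlation" else "required_total_n_80_power"

    def fmt3(v: float) -> str:
        return f"{round3(v):.3f}"

    def fmt_n(v: float) -> str:
        return "" if not np.isfinite(v) else f"{int(v):,}"

    out = pd.DataFrame(
        {
            "Relationship Strength": [
                f"{s} ({x:g})"
                for s, x in zip(table["relationship_strength"], table["link_strength"])
            ],
            "Number of Intermediate Links": table["n_intermediate_links"],
            "Estimate": table[est_col].map(fmt3),
            "95% CI": [
                f"{fmt3(lo)}, {fmt3(hi)}"
                for lo, hi in zip(table["ci_lower"], table["ci_upper"])
            ],
            "N for 80% Power": table[n_col].map(fmt_n),
        }
    )
    return out
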