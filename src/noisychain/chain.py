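"""Linear-Gaussian causal chains from a distal skill to reading ability.

The generative model is a chain of standardized skills.  The most distal
skill (Skill A) is standard normal; every subsequent skill is a weighted
mixture of the previous skill and fresh standard-normal noise standing in
for all of that skill's other determinants:

    Skill A  ~ N(0, 1)
    Skill L  =  x_L * input_{L-1}  +  y_L * eps_L,   eps_L ~ N(0, 1)

with ``x_L + y_L = 1``.  The last link in the chain is reading ability.
A chain with ``k`` intermediate links has ``k + 2`` skills and ``m = k + 1``
generative steps.

Because the mixture weights do not sum in quadrature, the variance of each
successive skill shrinks, and what exactly feeds the next link matters.
Two propagation variants are supported:

``raw_weights``
    each link receives the previous skill exactly as generated
    (its variance below 1), so the chain correlation is
    ``x**m / sqrt(V_m)`` with ``V_m = x**2 * V_{m-1} + y**2``;

``standardized_input``
    each skill is rescaled to sample mean 0 / sd 1 before it feeds the
    next link, so every step contributes the same per-step correlation
    ``x / sqrt(x**2 + y**2)`` and the chain correlation is that value
    to the power ``m``.

The two variants coincide for a direct relationship (``k = 0``) and
diverge for longer chains.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ChainValidationError, DegenerateInputError

RAW_WEIGHTS = "raw_weights"
STANDARDIZED_INPUT = "standardized_input"
_VARIANTS = (RAW_WEIGHTS, STANDARDIZED_INPUT)

__all__ = [
    "RAW_WEIGHTS",
    "STANDARDIZED_INPUT",
    "ChainSpec",
    "MonteCarloDesign",
    "SkillPanel",
    "draw_skill_panel",
    "standardize_columns",
]


@dataclass(frozen=True)
class ChainSpec:
    """Parameters of one noisy causal chain.

    Parameters
    ----------
    link_strengths : sequence of float
        Mixture weights ``x_1 .. x_m``, one per generative step, each in
        ``[0, 1]``; the chain has ``m - 1`` intermediate links.  The noise
        weight of step L is ``1 - x_L``.
    propagation_variant : {"raw_weights", "standardized_input"}
        Whether each skill feeds the next link as generated, or is
        standardized first (see module docstring).
    """

    link_strengths: tuple[float, ...]
    propagation_variant: str = RAW_WEIGHTS

    def __init__(
        self,
        link_strengths: Sequence[float],
        propagation_variant: str = RAW_WEIGHTS,
    ) -> None:
        object.__setattr__(self, "link_strengths", tuple(float(x) for x in link_strengths))
        object.__setattr__(self, "propagation_variant", propagation_variant)
        self._validate()

    def _validate(self) -> None:
        if len(self.link_strengths) < 1:
            raise ChainValidationError("a chain needs at least one link (Skill A -> reading)")
        for x in self.link_strengths:
            if not np.isfinite(x) or not 0.0 <= x <= 1.0:
                raise ChainValidationError(f"link strength {x!r} outside [0, 1]")
        if self.propagation_variant not in _VARIANTS:
            raise ChainValidationError(
                f"unknown propagation variant {self.propagation_variant!r}; "
                f"expected one of {_VARIANTS}"
            )

    @classmethod
    def constant(
        cls,
        x: float,
        n_intermediate_links: int,
        propagation_variant: str = RAW_WEIGHTS,
    ) -> "ChainSpec":
        """Chain with the same link strength ``x`` at every step.

        ``n_intermediate_links = k`` gives ``k + 1`` generative steps.
        """
        k = int(n_intermediate_links)
        if k < 0:
            raise ChainValidationError("number of intermediate links must be >= 0")
        return cls((float(x),) * (k + 1), propagation_variant)

    @property
    def noise_weights(self) -> tuple[float, ...]:
        """Noise weights ``y_L = 1 - x_L`` for each step."""
        return tuple(1.0 - x for x in self.link_strengths)

    @property
    def n_intermediate_links(self) -> int:
        return len(self.link_strengths) - 1

    @property
    def n_steps(self) -> int:
        """Number of generative steps ``m = k + 1``."""
        return len(self.link_strengths)

    @property
    def n_skills(self) -> int:
        """Number of columns in a panel: Skill A, intermediates, reading."""
        return len(self.link_strengths) + 1

    @property
    def column_names(self) -> tuple[str, ...]:
        letters = [f"Skill_{chr(ord('A') + i)}" for i in range(self.n_skills - 1)]
        return tuple(letters + ["Reading"])


@dataclass(frozen=True)
class MonteCarloDesign:
    """Sampling design of a Monte-Carlo study.

    ``n_participants`` is the sample size of each simulated study and
    ``n_replications`` how many independent studies are simulated; the
    summary statistics are the mean and the central ``ci_level`` empirical
    quantiles over replications.  ``rng_seed`` fixes the whole run.
    """

    n_participants: int
    n_replications: int
    rng_seed: int = 0
    ci_level: float = 0.95

    def __post_init__(self) -> None:
        if self.n_participants < 4:
            raise ChainValidationError("need n_participants >= 4 for a defined correlation")
        if self.n_replications < 1:
            raise ChainValidationError("need at least one replication")
        if not 0.0 < self.ci_level < 1.0:
            raise ChainValidationError("ci_level must be in (0, 1)")


@dataclass
class SkillPanel:
    """A participants-by-skills score matrix.

    Columns are ordered Skill A, Skill B, ..., Reading.
    """

    scores: np.ndarray
    column_names: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2:
            raise ChainValidationError("panel scores must be a 2-D matrix")
        if not self.column_names:
            self.column_names = tuple(f"col_{i}" for i in range(self.scores.shape[1]))
        if len(self.column_names) != self.scores.shape[1]:
            raise ChainValidationError("one name per column required")

    @property
    def n_participants(self) -> int:
        return self.scores.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, columns=list(self.column_names))

    def to_csv(self, path, sep: str = ",") -> None:
        """Write one row per participant with headered columns."""
        self.to_frame().to_csv(path, sep=sep, index=False)


def _zscore(a: np.ndarray, axis: int = 0) -> np.ndarray:
    """Sample z-score along ``axis`` (ddof=1); raises on zero variance."""
    mean = a.mean(axis=axis, keepdims=True)
    sd = a.std(axis=axis, ddof=1, keepdims=True)
    if np.any(sd == 0):
        raise DegenerateInputError("zero-variance column cannot be standardized")
    return (a - mean) / sd


def simulate_chain_columns(
    spec: ChainSpec,
    n_participants: int,
    rng: np.random.Generator,
    n_replications: int = 1,
    keep: str = "all",
) -> np.ndarray:
    """Simulate chain scores for a block of replications.

    Returns an array of shape ``(n_replications, n_skills, n_participants)``
    when ``keep == "all"``, or ``(n_replications, 2, n_participants)`` with
    only Skill A and reading when ``keep == "ends"`` (memory-lean path used
    by the Monte-Carlo experiments).  Standardization of inputs under the
    ``standardized_input`` variant is per replication (sample mean/sd).
    """
    if n_participants < 1:
        raise ChainValidationError("need at least one participant")
    shape = (n_replications, n_participants)
    standardize_inputs = spec.propagation_variant == STANDARDIZED_INPUT
    current = rng.standard_normal(shape)
    first = current
    if keep == "all":
        columns = [current]
    for x, y in zip(spec.link_strengths, spec.noise_weights):
        feed = _zscore(current, axis=1) if standardize_inputs else current
        current = x * feed + y * rng.standard_normal(shape)
        if keep == "all":
            columns.append(current)
    if keep == "all":
        return np.stack(columns, axis=1)
    if keep == "ends":
        return np.stack([first, current], axis=1)
    raise ValueError(f"keep must be 'all' or 'ends', got {keep!r}")


def draw_skill_panel(
    spec: ChainSpec,
    n_participants: int,
    rng: np.random.Generator | int | None = None,
) -> SkillPanel:
    """Draw one panel of participant scores from the chain model.

    Column 0 is i.i.d. N(0, 1); each later column mixes the previous
    skill (raw or standardized, per ``spec.propagation_variant``) with
    fresh noise.  The last column is reading ability.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    block = simulate_chain_columns(spec, n_participants, rng, n_replications=1, keep="all")
    return SkillPanel(block[0].T, spec.column_names)


def standardize_columns(panel: SkillPanel) -> SkillPanel:
    """Rescale every column to sample mean 0 and sample sd 1.

    Pearson correlations between columns are unchanged.  Raises
    :class:`DegenerateInputError` if any column has zero variance.
    """
    return SkillPanel(_zscore(panel.scores, axis=0), panel.column_names)
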