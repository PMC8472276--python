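# Methods

## The model

`noisychain` simulates the relationship between a distal cognitive cause
(say, a domain-general statistical-learning ability) and reading ability
when the two are connected by a chain of intermediate skills. Every skill
is standard normal in the population; each link mixes the previous skill
with fresh standard-normal noise that stands in for all of that skill's
other determinants:

    Skill A ~ N(0, 1)
    Skill L = x_L * input(Skill L-1) + y_L * eps_L,   eps_L ~ N(0, 1)

with `x_L + y_L = 1` and the last skill interpreted as reading ability. A
chain with `k` intermediate links has `k + 2` skills and `m = k + 1`
generative steps. Because `x` and `y` sum to 1 rather than in quadrature,
each skill's variance is below 1, and what exactly feeds the next link
changes the implied population correlation between Skill A and reading:

- **raw_weights** — each link receives the previous skill as generated.
  The variance recursion is `V_L = x^2 V_{L-1} + y^2` with `V_0 = 1`, the
  covariance with Skill A is `x^m`, and the chain correlation is
  `rho = x^m / sqrt(V_m)`.
- **standardized_input** — each skill is rescaled to sample mean 0 / sd 1
  before feeding the next link. Every step then contributes the same
  per-step correlation and `rho = (x / sqrt(x^2 + y^2))^m`.

The variants coincide for a direct relationship (`k = 0`) and diverge for
longer chains. Both are first-class in the API because the two published
reference tables this package reproduces are internally consistent only
under different variants: the correlation table matches `raw_weights`
while the group-difference table matches `standardized_input`. The prose
description of the original simulations ("each skill was standardised")
does not pin down where standardization happened, so neither variant is
privileged; the table builders default to the variant that matches the
corresponding printed table, and the variant is always recorded in the
output provenance columns.

## Monte-Carlo experiments

**Correlation study.** Per replication: draw a panel of participants,
standardize each column, and record the Pearson correlation between
Skill A and reading. Defaults follow the reference design: 1,000
participants per replication, 10,000 replications.

**Case-control (dyslexia) study.** Per replication: draw a panel with
10,000 participants, standardize, classify participants with standardized
reading score `z < -2` as the dyslexia group (strictly below; the boundary
belongs to controls), and compute

    d = (mean_dyslexia - mean_control) / sd_all

on Skill A, where `sd_all` is the full-sample standard deviation (ddof=1),
not a pooled within-group sd. Replications in which either group is empty
are excluded from the summary and counted rather than resampled; at
10,000 participants the dyslexia group is empty with probability
`(1 - Phi(-2))^10000` ~ 1e-100, so the exclusion rule is immaterial at the
default design and only matters for deliberately small runs.

Summaries report the mean estimate over replications and the central 95%
empirical interval, computed as the 2.5th/97.5th percentiles with linear
interpolation between order statistics.

## Closed-form oracles

Every simulated quantity has an analytic companion used throughout the
tests:

- the chain correlation formulas above (cross-checked in the tests against
  an independent coefficient-vector propagation oracle);
- truncated-normal conditional means `E[Z | Z < c] = -phi(c)/Phi(c)` and
  `E[Z | Z >= c] = phi(c)/(1 - Phi(c))` (validated against adaptive
  quadrature to 1e-10);
- the expected case-control difference, from bivariate-normal conditional
  means: `d = rho * (E[Z | Z < c] - E[Z | Z >= c])`. At the default cutoff
  `c = -2` the slope is `-2.428463`, so `d` is proportional to the chain
  correlation with that constant.

## Power and sample size

`correlation_power` implements the bias-corrected Fisher-z approximation
used by `pwr.r.test`: critical `t` at `alpha/sides` with `n - 2` df, the
corresponding critical correlation `r_c = sqrt(t^2 / (t^2 + n - 2))`, the
transform `z(r) = atanh(r) + r / (2(n - 1))`, and normal comparison at
standard error `1/sqrt(n - 3)`. `two_sample_t_power` is exact noncentral-t
power for equal groups: `df = 2n - 2`, noncentrality `d * sqrt(n/2)`,
two-sided rejection mass beyond both central-t critical values.

Solvers invert these with Brent's method on a bracket expanded
geometrically from the large-sample closed-form guess; the bracket logic
steps over near-zero-df regions where the noncentral-t is numerically
indeterminate. Convergence is verified by requiring the achieved power at
the continuous solution to be within 1e-8 of the target.

**Rounding rules.** The continuous solutions are real numbers; the
reported integers follow the conventions that reproduce the reference
tables' verifiable cells: the correlation `n` is the floor of the
continuous solution (giving 170, 130, 44 at r = 0.213, 0.243, 0.408) and
the two-group total is twice the continuous per-group solution rounded to
the nearest integer (giving 45, 23, 13 at d = 0.859, 1.215, 1.717). Both
are unconventional — power analysts usually take ceilings — so the
continuous solution and the rule label are always returned alongside the
integer, and users can apply their own convention. Some published cells
follow no uniform rule: the very large sample sizes were evidently
computed from unrounded simulated estimates (a correlation of 0.0095
versus 0.009 changes the implied n by ~10%), and a few single-digit cells
are off by one from any rounding of the formula solution. The table
builders always size from the 3-decimal rounded estimate, which is the
reproducible convention.

## Randomness and determinism

One master seed governs a run. Table builders derive an independent
per-scenario seed via `SeedSequence([master, table_id, scenario_index])`,
so any scenario can be re-run on its own, in any order, with identical
results; replications within a scenario are consecutive blocks of that
scenario's stream. Identical seed and configuration give byte-identical
output files. Replication blocks are sized to hold roughly 5e6 draws per
chain column, bounding memory at ~100 MB for the largest default run.

## Scaling choices

The reproduction tables default to the reference design (10,000
replications). The test suite runs scaled versions — 1,000 replications
for the correlation grid and 500 for the spot-checked group scenarios —
whose Monte-Carlo standard errors (about 0.001 for mean correlations,
0.003 for mean d) are several times smaller than the test tolerances
(±0.01 and ±0.02 respectively). The acceptance script uses the full
10,000 replications for correlations and 1,000 for group studies.

## What the generator does and does not emulate

The generator reproduces the idealized study conditions: Gaussian skills,
linear links, constant link strength within a chain, and no measurement
error. Passing tests therefore show that the package computes this model
correctly, not that real reading-research data behave this way; in real
data, measurement error attenuates every correlation further, link
strengths vary across links, and selection into case groups uses noisy
composite criteria rather than a sharp z-cutoff on a single score. All of
these would make the published sample-size requirements *optimistic*.

## Degenerate inputs and edge cases

- Zero-variance columns cannot be standardized (`DegenerateInputError`);
  impossible for continuous draws, reachable only with constructed panels.
- `x = 1` chains are noiseless: all correlations are exactly 1 and sample
  sizes are reported as missing, since the solvers' domain is an effect
  strictly inside (0, 1). Likewise estimates rounding to 0.000 have no
  finite sample size and are reported missing.
- Group studies warn below 1,000 participants per replication and raise
  only if *every* replication lacks a case or control group.

## Known limitations

- The Fisher-z correlation power is an approximation; at very small n
  (< ~10) it can differ from exact power by more than the rounding rule's
  granularity, which is one reason single-digit published cells resist
  unit-exact reproduction.
- Only equal-group two-sample designs are supported, matching the
  reference calculation; real case-control studies selected at z < -2
  would naturally produce very unequal groups.
- No per-link heterogeneous tables: heterogeneous `link_strengths` are
  supported by the model API but the reproduction grids keep `x` constant
  within a chain.
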