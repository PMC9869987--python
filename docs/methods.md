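# Methods

## The measurement model

A determinant study in this toolkit measures each *generic determinant*
(attitude, perceived norm, perceived behavioral control in the
Reasoned-Action-Approach template) with one item per *subdeterminant facet*
(instrumental/experiential, injunctive/descriptive, capacity/autonomy), plus
one target item (intention), all on an integer Likert scale (default 1–5).
Composites are unweighted means of a determinant's items: with one item per
facet there is no empirical basis for differential weights, and equal
weighting keeps the composite in scale units. Reverse-coding is a per-item
flag applied before any scoring; items pass through unchanged by default.
Validation is listwise per behavior: any respondent with a missing,
non-integer, or out-of-range value in a required column is dropped and
counted. Re-validating a validated dataset removes nobody.

## Interval estimators

All estimation is interval-first: the outputs are points *with* confidence
intervals, because determinant selection should respond to the accuracy of
an estimate, not only its value.

- **Mean:** `m ± t_{(1+γ)/2, n−1} · s/√n`. Zero-variance input yields a
  zero-width interval flagged `degenerate` rather than an error.
- **Correlation:** Pearson r with the Fisher-z interval
  `tanh(atanh(r) ± z_{(1+γ)/2}/√(n−3))`, requiring n ≥ 4 and non-constant
  input. |r| = 1 returns a flagged degenerate interval.
- **Cohen's Q:** `atanh(r₁) − atanh(r₂)` with
  `Q ± z_{(1+γ)/2}·√(1/(n₁−3) + 1/(n₂−3))`; valid only for independent
  samples (passing the same data twice triggers a warning, not an error,
  since the arithmetic is still defined). The default level is 99% — the
  stricter "key estimate" level appropriate when dozens of intervals are
  reported simultaneously; every level is caller-overridable.
- **Standard deviation:** the chi-square interval
  `[s·√((n−1)/χ²_{(1+γ)/2}), s·√((n−1)/χ²_{(1−γ)/2})]`. It assumes
  normality; on 5-point Likert data it is an approximation (see
  Limitations).

Empirical coverage of all four interval types is verified by the coverage
harness (`coverage_experiment`), which replays the actual estimator
functions over ≥ 1,000 seeded replicates and reports the hit rate with its
binomial Monte-Carlo standard error.

## Reliability and dimensionality

McDonald's ω = (Σλ)²/[(Σλ)² + Σθ] comes from a single-factor
maximum-likelihood fit (scikit-learn's factor analysis on standardized
items). A Heywood case or non-convergence falls back to principal-axis
extraction with iterated communalities, and the result is flagged
(`extraction="principal_axis"`, `converged=False`). The ω interval is a
nonparametric percentile bootstrap over respondents (default 2,000
replicates, seed-controlled); the method is a pragmatic default, not the
only defensible one. The Spearman–Brown coefficient 2r/(1+r) covers
two-item scales, where a one-factor model is saturated and ω is not
identified. Dimensionality is screened by the eigenvalues of the item
Pearson correlation matrix with the Kaiser criterion (eigenvalues > 1);
eigenvalues always sum to the item count, a property the tests exploit.

## AIPE sample-size planning

The planner returns the smallest n whose confidence interval at the assumed
parameter value is narrower than a requested half-width. Because the
Fisher-z interval is asymmetric on the r scale, "half-width" is a
convention; the default is **half the total width**, with `max_arm` (the
longer arm) available as an alternative. An expected-width convention
(averaging over the sampling distribution of r) is documented but not
implemented. The search is a linear scan upward from the smallest feasible
n (4 for correlations, 2 for SDs) — cheap, and immune to root-finding
trouble where tanh saturates. Minimality (n passes, n−1 fails) is asserted
by brute force in the tests. With the default convention the planner gives
205 for ρ=.80, w=.05 and 378 for ρ=.10, w=.10 at 95%.

For standard deviations the same scan over the chi-square interval gives
n = 15 for σ = 0.7, w = 0.3 at 95%. Published tabulations sometimes quote
14 for these settings; no half-width convention we examined (half-total or
max-arm at 14 both exceed 0.3) reproduces that figure, so the planner
reports its own honestly-derived minimum rather than forcing agreement.
Power analysis for factorial ANOVA is out of scope: the design helpers only
enumerate factorial terms (2^f − 1 per outcome) and divide alpha across
outcomes (Bonferroni).

## Synthetic data

Likert responses are latent multivariate normal: unit SDs, a user-supplied
correlation matrix over the items (checked for symmetry, unit diagonal, and
positive semi-definiteness), and per-item latent means *calibrated* (by
root-finding on the closed-form discretized expectation) so that the
discretized item means converge to the requested targets. Discretization
rounds to the nearest scale point — fixed cut-points at half-integer
boundaries. Targets at the scale bounds are infeasible under a unit-SD
latent normal and raise an error. Discretization attenuates correlations;
the attenuation is quantified by a large-n simulation oracle in the tests
rather than corrected, so the generator's *latent* correlation is an upper
bound on the observed one. The stock `study_conditions_response_spec`
emulates an eight-behavior 2×2×2 hi/lo factorial layout (defaults: low
mean 2.0, high mean 4.0, target mean 3.0, determinant–target latent r 0.4,
n = 415) — a realistic proof-of-concept configuration for this design.

Expert estimates are independent normal draws per parameter, rounded and
clamped to the integer 1–5 columns of an array question. Rounding nudges
the population SD of the discretized scores (1.009 for σ = 1 around a mid-
scale mean); recovery tests cover that discretized truth, not the latent σ.

What the generator does **not** emulate: respondent-level dependence across
behaviors (each behavior's block is drawn independently, whereas real
within-subjects data correlate across behaviors), ordinal response styles
(acquiescence, extreme responding), dropout, and item non-invariance.
Passing tests therefore validate the estimators and the pipeline, not any
claim about real populations.

## Plots

Plot construction is split from rendering. `build_*` functions emit
declarative, serializable `PlotModel` objects — bars, light-gray difference
segments, CI diamonds, dots, markers, reference lines, axis labels — and
all tests assert on these models, never on pixels. The central model maps
two axes onto one panel: bars in scale units rising from the scale minimum
(a 1–5 scale has no meaningful zero), diamonds in correlation units on a
[−1, 1] axis placed affinely over the same span, with the zero-correlation
gridline drawn. Diamonds are 4-vertex polygons with the extreme vertices
exactly at the CI bounds and the widest point at the estimate, echoing
meta-analysis summary diamonds; deliberately no whiskers, so attention goes
to the interval as a whole rather than its endpoints. Everything is
grayscale and raw data points are omitted by design (the expert plot is the
exception: individual expert dots with seed-controlled uniform jitter of
±0.3 column widths). Exact gray values and the diamond half-height are
style constants with documented defaults, not estimates. `render` is the
only backend-dependent step (matplotlib Agg; SVG output is byte-stable via
a fixed hash salt and stripped date metadata).

## Numerical choices and degenerate inputs

- Zero-variance input: flagged degenerate intervals wherever the value is
  still defined; hard errors only where the statistic is undefined
  (correlation of a constant, Spearman–Brown at r = −1, ω with a constant
  item).
- Sample correlations are clipped to [−1, 1] to absorb floating-point
  round-off on collinear input.
- Pearson r on tied Likert scores needs no special treatment; rank-based
  alternatives are out of scope.
- Every random routine takes an explicit seed and builds its own
  `numpy.random.Generator`; no global state.

## Problem sizes used in the checks

The test suite and acceptance script size their simulations for a
single-CPU run: coverage checks use 10,000 replicates at n = 200 (binomial
MC error ≈ 0.2 percentage points at the 95% level), closed-form recovery
checks use n = 20,000–200,000 draws, generator mean-recovery uses
n = 100,000 (tolerance 0.02 scale units), and the expert-SD recovery loop
uses 250–300 panels of 45 experts.

## Known limitations

- The chi-square SD interval and the normal-theory Q interval are derived
  under normality; on coarse Likert data they are approximations (the
  platykurtosis of a clamped-rounded normal makes the SD interval mildly
  conservative — its coverage in the tests is at or above nominal).
- ω's bootstrap CI ignores model misfit: it reflects sampling variability
  of the one-factor estimate only.
- The latent-normal response model is a stand-in for data generation and
  testing, not a substantive claim about how people answer Likert items.
- The AIPE planner plans at an assumed parameter value; it provides no
  assurance probability that the realized interval will be narrow enough.
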