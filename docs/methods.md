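# Methods

## Scope and data model

The package operates on unit-level cumulative-release matrices: one product,
`n` tablet units, a strictly increasing grid of sampling times in minutes,
release as a percentage on the 0–100 scale (values up to 120 are accepted to
tolerate assay overshoot; negatives are rejected). The canonical file format
is long CSV (`product, unit, time_min, release_pct`); writing uses `%.17g`
floats and reading uses round-trip parsing, so a write/read cycle is
bit-exact. Profiles are never interpolated: all comparisons happen at
measured time points, by default 60, 240 and 480 min — the early/middle/late
anchors at which the reference product releases roughly 30, 60 and 80 %.

## Similarity factor and its unbiased variant

For mean profiles compared at `P` points, `f2 = 100 − 25·log10(1 + msd)`
with `msd` the mean squared per-point difference; the log is base 10 (the
familiar 50–100 similarity range only arises in base 10). E(f2) replaces
`msd` with the per-point average of `(χ_t − χ_r)² + (s_t² + s_r²)/n`,
which is the unbiased estimate of the squared mean difference at each point;
the 1/P factor therefore averages the variance penalty together with the
squared differences. Because the typeset forms of this statistic vary in
where the 1/P binds, `f2_expected(..., scale_variance_by_p=False)` switches
to adding the raw variance sum instead. With unequal unit counts the smaller
`n` is used in the penalty (conservative). E(f2) ≤ f2 always, with equality
exactly at zero variance.

## Bootstrap intervals

The resampling unit is the whole tablet — its entire time vector — drawn
with replacement within each product, preserving both sample sizes; this
keeps within-tablet correlation intact, which per-time-point resampling
would destroy. Each replicate consumes randomness in a fixed, documented
order (test indices then reference indices from a single seeded numpy
Generator), so an independently coded loop with the same seed reproduces
the replicate stream exactly — that is how the test suite cross-checks the
implementation. Defaults: B = 500 replicates and a two-sided level of
α = 0.10 (90 % interval); beyond 500 replicates the bootstrap mean moves by
well under 0.5 f2 units on the standard fixture, which the suite asserts.

Percentile bounds use the empirical-CDF (type-1) quantile at 1-based index
⌈B·level⌉, avoiding interpolation ambiguity at B = 500. The BCa interval
shifts the quantile levels by the bias constant `z0 = Φ⁻¹(#{θ* < θ̂}/B)`
(replicates exactly equal to θ̂ counting half, a symmetric tie rule) and the
acceleration `a = Σ(θ̄−θᵢ)³ / [6(Σ(θ̄−θᵢ)²)^{3/2}]` from a delete-one
jackknife over the combined unit list (delete one test unit with the
reference intact, or vice versa; n_t + n_r leave-one-out values). With
z0 = a = 0 the BCa levels collapse to α/2 and 1−α/2 exactly. When the
replicate distribution is degenerate (all values identical, or θ̂ outside
its support) z0 is undefined: the result is flagged and the BCa bounds fall
back to the percentile bounds.

**Decision rule.** A test product is equivalent to the reference iff the
sample f2, the PI lower bound and the BCa lower bound all *strictly* exceed
the cutoff (default 50). The decision record lists which criteria failed,
so borderline formulations (sample f2 above 50 but an interval bound below)
are eliminated with an explicit reason.

## Release kinetics

Fits act on the mean curve across units, not per unit. Zero-order and
Higuchi are fitted through the origin (`Q = k·t`, `Q = k·√t`); first-order
pins the intercept at ln(100) and fits only the slope of
`ln(100 − Q) = ln(100) − k·t`, excluding points with Q ≥ 100; the power law
is fitted as `log10(Q/100) = log10 k + n·log10 t` restricted to
0 < Q ≤ 60 %, since the power-law approximation holds only in the early
portion of release. R² is reported on each model's own fitting scale
against the centered total sum of squares — it can be negative for a badly
misspecified origin-constrained model but never exceeds 1 — and is *not*
back-transformed, matching how such model-comparison tables are
conventionally produced. Model selection takes the maximal R², breaking
exact ties toward the model with fewer parameters. Mechanism classification
from the exponent: n < 0.45 Fickian diffusion, 0.45 ≤ n ≤ 0.89 anomalous
transport, n > 0.89 case-II transport; the 0.45 boundary is assigned to the
upper class.

## Designs and response models

Factors are cetyl alcohol mass A (mg) and HPMC K15M proportion B (% of
total tablet mass), coded as `a = (A − Ā)/(ΔA/2)` so corners sit at ±1. The
screening design is a 2² full factorial with configurable replicates and
center points (default 2 + 2 → 10 runs); the optimization design is the
face-centered central composite: 4 corners, 4 face-centered axial points
(±1, 0)/(0, ±1), and center points (default 2 → 10 runs). Run order is
randomized under a seed and stored for provenance; fitting ignores it.

Response models (linear: intercept, a, b; quadratic: + ab, a², b²) are
ordinary least squares on coded levels via statsmodels, reporting the
whole-model F-test and per-term t-tests — on these orthogonal designs this
coincides with partial (type-III-style) ANOVA, and no further replication of
commercial DoE software internals is attempted. R² and adjusted R² are
reported as percentages. Actual-unit coefficients come from exact algebraic
substitution of the coding transform into the coded polynomial, so the coded
and actual forms agree to machine precision at every point; both are derived
from the *same* fit and internal consistency is guaranteed rather than
matching any externally rounded pair of printed equations. A constant
response yields zero slopes with the whole-model p-value flagged undefined;
a rank-deficient design (e.g. a quadratic request on corner-only runs, where
a² is confounded with the intercept) raises an error naming the first
unestimable term.

Prediction evaluates the actual equations, clipping to [0, 100] only at
prediction time (never during fitting) with a flag, and flags extrapolation
outside the fitted ranges without refusing it. Predicted f2 applies the
similarity transform to the predicted (R1, R2, R3) against user-supplied
reference means — the reference's exact means are an explicit input, not a
built-in constant. The minimal-polymer solve runs bisection on
`predicted_f2(B) − cutoff` at fixed A to 10⁻⁴ percentage points; since f2
is monotone in B over the fitted range the root is bracket-independent.
RMSEP is `sqrt((1/n)·Σ(yᵢ − ŷᵢ)²)` over an external validation set.

## Mass balance, swelling, erosion

Both HPMC and magnesium stearate are dosed as percentages of the *total*
tablet mass, so `total = (drug + cetyl)/(1 − hpmc/100 − mgst/100)`. This
convention reproduces the published tablet masses of 16 of the 17 designed
formulations within 0.14 mg (one published value deviates by 0.5 mg and is
presumed a transcription slip; it is asserted as-is and allowed to fail
rather than "corrected"). Swelling is `(swollen − initial)/initial·100`,
erosion `(initial − dried)/initial·100`; physically implausible directions
(weight loss while swollen, dried weight above initial) return negative
percentages and are flagged, not rejected, since blotting and drying
introduce real measurement error.

## Synthetic data generator

The generator defines the study conditions under which everything is
tested: 12 units per run on the ten-point grid 15–1440 min; a power-law
mean curve `Q(t) = min(cap, k·t^n)` with k on the percent-per-minⁿ scale;
additive zero-mean Gaussian noise per unit and time point with default SD
2 percentage points (consistent with the per-time-point SDs visible in
12-unit dissolution runs of this kind); running-maximum monotonization and
clipping to [0, cap]. The default reference curve passes exactly through
(60 min, 30 %) and (480 min, 80 %) — solving the two-point log-log system
gives n ≈ 0.4717, k ≈ 4.349 — and releases ≈57.7 % at 240 min, i.e. "about
60 %"; the reference's 240-min value is deliberately derived from the curve
rather than forced. The default seed is 20210808.

What the generator does *not* emulate: correlated errors across time within
a tablet (noise is independent per time point before monotonization),
apparatus effects, assay drift, or tablet-to-tablet variation in the
underlying curve parameters. Passing tests therefore demonstrate the
statistics are implemented correctly under an idealized noise model, not
that real dissolution data satisfy that model. Monotonization makes the
noise slightly non-zero-mean where adjacent mean increments are small
relative to the noise SD (the early grid points); the comparison time
points 60/240/480 min have increments an order of magnitude above the
default noise SD, where the effect is negligible — the coverage and
convergence tests exploit this.

## Problem sizes and numerical choices

The test suite uses the study-scale configuration throughout: 12+12 units,
B = 500 bootstrap replicates, 200 simulated dataset pairs for interval
coverage, 100 seeded curves for exponent recovery, 200 repeats for the
coefficient-recovery and model-selection properties — sizes at which every
stochastic assertion holds with margin and the whole suite runs in a few
seconds. Bisection tolerance 10⁻⁴ %, coded/actual agreement asserted at
10⁻⁹, all randomness through seeded `numpy.random.default_rng`.

## Known limitations

- Equivalence testing is the bootstrap-f2 rule only; no parametric f2
  intervals, no f1 difference factor, no regulatory 85 %-release truncation
  rules beyond configurable time points.
- Kinetics offers the four classical models only (no Weibull,
  Hixson–Crowell, Hopfenberg) and no AIC-based selection.
- The DoE layer covers two factors with linear/quadratic models; no
  desirability-function multi-response optimization, blocking, or Box–Cox
  transforms.
- No floating/buoyancy or pharmacokinetic simulation: floating behavior,
  like the dissolution measurements themselves, is experimental input.
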