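# Methods

## Density-response models and the plausibility screen

The package models two responses of maize to planting density x
(plants m⁻²), both on a relative-yield scale (yield divided by the mean
yield at a reference density, which removes variety and year scale
differences):

* **Population (per-area) relative yield** — rises to a single interior
  optimum and falls under crowding.  The selected family is the Hoerl
  curve `y = a·bˣ·xᶜ` with a > 0, 0 < b < 1, c > 0: `a` scales the
  pre-optimum yield range, `b` is the post-optimum decline base, `c` the
  pre-optimum rise exponent.  Its change rate `a·bˣ·x^(c−1)(x·ln b + c)`
  vanishes at the optimal density x* = −c/ln b, the package's headline
  density-resistance statistic.
* **Single-plant relative yield** — declines monotonically.  The selected
  family is the Weibull-type curve `y = m − n·e^(−p·xᵗ)` (p > 0, and
  t < 0 for all fitted varieties), falling from plateau `m` to asymptote
  `m − n`.

The catalog (`densyield.catalog`) registers 22 families — every family in
the published population and single-plant rankings, de-duplicated, with
role tags.  Model selection is *not* by goodness alone: the screen
(`densyield.plausibility`) accepts a population curve only if
lim x→0⁺ y = 0, lim x→∞ y = 0 and the curve has exactly one interior
maximum.  Limits are computed from per-family symbolic rules (never
numerically), and unimodality analytically for Hoerl (equivalent to its
admissibility constraints) or by derivative sign-change counting on a
1000-point log grid over [10⁻³, 10³] otherwise.  The single-plant screen
is this package's codified reading (the source literature only asserts the
Weibull family's suitability): bounded and non-increasing across the
design range with a finite non-negative asymptote.

Two catalog notes.  First, the four-parameter sigmoid printed as
`a/(1+e^(b−cx)^(1/d))` is typeset ambiguously; it is implemented in the
standard Richards reading `a/(1+e^(b−cx))^(1/d)` and the ambiguity is
flagged in the model's docstring.  Second, the screen correctly admits
the reciprocal-x power-exponential forms `a·b^(1/x)·x^c` (b<1, c<0) and
its `exp(a + b/x + c·ln x)` reparameterisation alongside Hoerl — they are
also unimodal with both tails at zero — but they rank below Hoerl on SD,
so selection is unaffected.

## Fitting

`densyield.fitting` minimises the residual sum of squares with scipy's
trust-region-reflective least squares under each family's box bounds.
Because several families are multimodal, fits restart from a
deterministic multistart set: data-driven linearised starts (log-linear
regression for the power-exponential families, linearised rational
forms, polynomial solves), per-family lattices for the sigmoids, plus
seeded log-normal jitter up to `n_starts` (default 32).  Re-fitting with
the same seed and options is bit-reproducible.  On noise-free
model-generated data the generating parameters are recovered to ~1e-6
relative.

Goodness statistics follow the conventions of the classic curve-fitting
tools in this literature: `SD = sqrt(SSE/(n−k))` (standard error of the
estimate) and `r` = Pearson correlation of observed vs fitted.  The
published tables head this column "R²" but quote the same values as r in
text; the package computes and labels it r.  Significance stars come
from the two-sided t-test on r with n−2 df (** p<0.01, * p<0.05),
computed rather than read from critical-value tables so n can vary.
Ranking is SD ascending, ties broken by r descending then by fewer
parameters; per-family failures become flagged entries instead of
aborting a ranking.

Replicates are fitted as individual records by default (density-level
means are an option); with a balanced design the least-squares solution
is the same either way.

## Normalisation and design arithmetic

`normalize` divides yields by the mean yield at a reference density
within each variety/year group.  The default reference is the minimum
density present per group; a fixed reference (e.g. `fixed:3.33`) is
supported because the source study anchored at 3.33 plants m⁻² (the
minimum present in its 2010 trial — consistently, the published
per-variety curves evaluate to ≈1.0 at x = 3.33).  The choice rescales
only `a`, so x* and the resistance ordering are unaffected.

`spacing_to_density` converts a row spacing to density as
1/(mean line spacing × row spacing) with one plant per grid position;
the alternating 80/40 cm lines give the design's mean 60 cm spacing and
reproduce the printed 13-density list.

## Resistance and verification analytics

* `optimal_density`: closed-form −c/ln b, cross-checked in tests against
  a brute-force grid argmax (step 1e-4 on (0, 50]).
* `resistance_ranking`: descending x*; ties by peak relative yield, then
  label.
* `single_plant_decline`: the "average rate of decline" is codified as
  the endpoint secant (y(x_lo) − y(x_hi))/(x_hi − x_lo) over the design
  range 1.67–16.67 plants m⁻², the simplest defensible reading of an
  otherwise undefined metric.  Note that under this metric a slow-tailed
  curve can shed the most total relative yield over the range even if it
  declines most slowly at low density, so orderings quoted under other
  (undefined) readings need not be reproduced.
* `verify_against_standard`: rescales the fitted relative curve to
  absolute g m⁻² by the standard plot's mean yield at its reference
  density, regresses measured on simulated (OLS), reports the squared
  correlation as accuracy plus per-density percent deviations
  (100·(simulated − measured)/measured, 2-decimal rounding).  With only
  four densities spanning a nearly flat stretch of the curve the r² of a
  single plot is noisy; per-density deviations are the sharper check.

Reported parameters and optima are rounded to 4 decimals, deviations to
2, mirroring the published precision.  Recomputing −c/ln b from published
4-decimal parameters reproduces the published optima to ~3·10⁻⁴ relative
(the originals were evidently computed before rounding).

## Synthetic trial generator

`densyield.synthetic` makes every stage testable without the undeposited
field data.  Defaults are the study's stated conditions wherever stated:

* 13 design densities; per-variety Hoerl and Weibull truths and additive
  Gaussian noise sds equal to the published per-variety fits and their
  SDs (population 0.0533–0.1419, single-plant 0.0146–0.0475);
* published double-ear profiles (non-increasing in density; Bernoulli
  per plant, 10 plants scored per replicate);
* 4 replicate yield records per density (the study sampled four rows per
  plot); multi-year runs draw a shared multiplicative year effect
  (sd 0.02) that the normalisation stage removes exactly — closure and
  recovery analyses simulate 5 years, the study's duration;
* single-plant yields truncated at zero.

Package choices where the study states none: reference absolute yield
800 g m⁻² at relative yield 1 and single-plant scale 320 g (placing
simulated yields in the published 850–1030 g m⁻² range); ear/morphology
trait means drift linearly in log density between realistic endpoints
(ear length 20→14.5 cm, bald tip 0.4→2.8 cm, perimeter 16→13.2 cm,
thousand-kernel weight 340→255 g); plant height approaches its maximum
as H(1 − 0.3e^(−0.4x)), ear/plant height ratio rises 0.40→0.50, stem
diameter tapers 35% across the range — parameterised so the
morphological-index ratios at x* fall in the reported field ranges.

`simulate_trait_table` draws correlated trait records from a target
correlation matrix (eigen-factor transform of a validated symmetric PSD
target).  The default target follows the published ear-trait matrix,
which as printed is **not** positive semidefinite (min eigenvalue
−0.54, and one yield pair is not printed, filled at −0.20); the default
is its nearest-PSD projection (eigenvalue clipping, unit-diagonal
rescale), so default empirical correlations match the published signs
and approximate magnitudes, not the exact printed entries.

What the generator does **not** emulate: field spatial structure and
border effects, weather/soil covariates, genotype × year interaction
beyond a scalar year effect, heteroscedastic or non-Gaussian errors, and
any mechanistic crop growth.  Passing tests therefore demonstrate the
statistical machinery under the assumed error model, not agronomic
validity on new field data.

## Numerical choices

* Evaluation is overflow-safe: exponential families run in log space
  with exponents capped at 709, so limit probes at x = 10⁻⁸ and 10⁸
  return 0/inf instead of raising.
* Analytic derivatives for Hoerl, Weibull and the polynomials; central
  finite differences (relative step 1e-6) otherwise, agreeing with an
  independent difference to 1e-6 / 1e-4 relative in tests.
* Fit bounds shave 1e-9 off open interval endpoints; non-convergence of
  all starts yields a flagged result (sd = inf), never an exception
  inside a ranking.
* Oscillatory families report `nan` for a nonexistent limit at infinity
  and are rejected by the screen with an explicit reason.
* Ties in `rank_fits` finally break on the family id for determinism.

## Problem sizes

Test-suite and acceptance-script simulations use 13 densities × 4
replicates × 5 years per variety (260 records), 50-replicate recovery
envelopes (30 in the acceptance script) and 100-replicate closure runs;
the full candidate catalog is exercised per fit in the fitting tests and
a three-family set (the published top three: cubic, rational, Hoerl) in
the replicated pipeline runs, which screens and selects identically.

## Known limitations

* The x* estimator's sampling spread at the published noise levels
  (Monte-Carlo sd 0.10–0.19 plants m⁻² under the design above) is of the
  same order as the gaps between adjacent published optima (0.36–0.39
  plants m⁻²), so the full five-variety resistance ordering reproduces in
  ≈93–94% of seeded replicates, not essentially always; distinguishing
  adjacent varieties reliably needs more replication than the gradient
  design provides.
* The single-plant "average decline" metric is a package codification;
  see above.
* Pairwise-complete correlations can yield a non-PSD matrix on patchy
  data; entries are still reported per pair (constant columns are
  flagged undefined, never zero).
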