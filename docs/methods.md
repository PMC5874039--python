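# Methods

## The procedure

The package implements a two-part protocol. First, *hindcast validation*:
an SDM fitted on a species' present-day occurrences is projected onto
paleoclimate slices matching the calibrated age of a dated fossil of that
species; the model "passes" if the suitability it assigns to the fossil's
cell, `S`, reaches the minimum suitability it assigns to any present-day
occurrence cell, `m`. Second, *taxonomic assignment*: for a fossil
identified only to genus, the same comparison is run for every candidate
species; candidates with `S ≥ m` are plausible, plausible candidates are
ranked by `S`, and the top candidate (if clearly ahead) is the headline
assignment.

Both parts assume distribution–climate equilibrium (the species occupies
the climates suitable for it) and niche conservatism over the modelled
span. The comparison is deliberately *not* probabilistic: it asks whether
the fossil site was at least as climatically suitable as the worst site
the species demonstrably tolerates today.

## Models

All three models consume a presence sample and a contrast sample
(random background for Maxent, random pseudo-absences disjoint from the
occupied cells for GLM/RF) extracted at grid-cell resolution.

**Maxent** (authored here). A Gibbs density over the background cells,
`q(x) ∝ exp(w·f(x))`, with features `f` = per-variable linear and
quadratic terms of z-scored variables (z-scoring against the background
sample, stored and replayed at prediction). The weights minimize the
regularized presence negative log-likelihood; the L1 penalty per feature
is `λ_j = rm · s_j · √(2 ln p / n)` with `s_j` the feature spread over the
presences, `p` the feature count, `n` the presence count and `rm` the
user-facing regularization multiplier (default 1). The universal-rate
factor makes the penalty strong enough that a presence sample
indistinguishable from background yields an (almost exactly) flat
suitability surface, while leaving genuine niche signal essentially
unpenalized. The L1 problem is solved exactly by positive/negative weight
splitting under L-BFGS-B bounds; an iteration cap (default 1000) and
convergence tolerance (default 1e-5) apply, and a non-converged fit is
returned with a flag and a warning rather than an error. Output uses the
classical logistic transform `p = e^H q/(1 + e^H q)` (`H` = entropy of
the fitted density over the background), with cloglog available.
Restricting features to linear + quadratic keeps the optimization convex
and the fitted log-density a quadratic form — the same family as a
Gaussian niche — and keeps the three algorithms comparable.

**GLM.** Binomial likelihood, logistic link, linear + quadratic terms,
fitted by maximum likelihood (statsmodels) on the raw variable scale so
coefficients are directly interpretable. Complete separation (detected
via the IRLS separation warning, non-finite or exploding coefficients, or
non-convergence) triggers a small-ridge refit (`alpha = 1e-6`) with a
warning instead of a failure.

**Random forest.** scikit-learn `RandomForestClassifier`, 500 trees
(the conventional stabilization point — doubling the trees changes mean
predictions by < 0.05), seeded for bit-reproducibility. Suitability is
the mean per-tree presence probability; `min_samples_leaf` defaults to 5
so leaves carry genuine probability estimates rather than pure 0/1 votes,
matching how forests are read as continuous suitability surfaces (the
R-randomForest regression nodesize convention). With fully-grown trees
the surface far from the niche collapses into ties; leaf size 5 restores
a usable gradient there. Exposed as a parameter.

**Clamping** (truncating projection-time variables to their training
range) is applied inside the prediction path of every model, per-call
toggleable and on by default. Consequences: projecting the present-day
slice reproduces `predict_map` bit-for-bit, clamped and unclamped
predictions agree wherever no variable exceeds the training range, and
predictions in non-analogue climate saturate at the range edge — which is
precisely why MESS diagnostics accompany every assignment (see below).

## Evaluation

AUC is the exact Mann–Whitney statistic (ties counted ½), not a curve
integration — this removes discretization ambiguity and lets tests verify
it against brute-force pair enumeration. TSS(t) = sensitivity +
specificity − 1 with "positive" meaning score ≥ t, maximized over all
distinct observed scores and midpoints; the smallest maximizing threshold
is reported for audit. Cross-validation repeats a seeded 75/25 split
(default 50 repetitions) of presences and contrast points together,
refitting on the training portion and scoring the holdout; failed
repetitions are skipped and counted, with > 20% failures escalating to an
error. Note that max-TSS is positively biased on small holdouts (it is a
Kolmogorov–Smirnov-type statistic), which is why signal-free data scores
mean TSS ≈ 0.1 rather than 0 at these test sizes.

## Non-analogue climate diagnostics

MESS follows the standard piecewise definition: with `f` the percentage
of reference values strictly below the projected value `v`, similarity is
`(v−min)/(max−min)·100` (f = 0), `2f` (0 < f ≤ 50), `2(100−f)`
(50 < f < 100) or `(max−v)/(max−min)·100` (f = 100); MESS is the minimum
over variables and MoD its argmin (lowest index on ties). Strictly-below
counting makes the hand cases exact; a consequence worth knowing is that
the similarity at the median of an odd-sized reference sample is slightly
below 100 (it equals 100 exactly when the strictly-below fraction is one
half). The reference sample is the model's training table (presences plus
contrast points); a model rebuilt from its serialized JSON retains only
per-variable ranges, which still flag out-of-range (negative-MESS) cells.
MESS/clamping status at the fossil cell is attached to every assignment
row as a caveat.

## Fossil age matching

Climate slices are matched to a fossil's calibrated age interval by a
±500-year window: every slice whose nominal age (k·1000 yr BP) falls
within [age_min − 500, age_max + 500] is evaluated, with a guaranteed
non-empty fallback to the single nearest slice. Published case studies of
this kind round fossil ages to slices in more than one way; a fixed,
documented window was chosen over replicating any one paper's rounding.
Per-slice suitabilities collapse to `S` by maximum (mean available as an
option): a fossil needed suitable climate at *some* moment of its age
interval. Plausibility uses `≥` so that `S = m` passes. When `m = 0`
(degenerate model), the ratio `S/m` is reported as a sentinel and
plausibility falls back to `S > 0`. Headlines require the top two
plausible candidates to differ by at least `tie_tolerance` (default
0.01), otherwise "indeterminate". Per-algorithm reports stay separate;
the pipeline adds a consensus line (count of algorithms agreeing).

## The virtual-species generator

Each scenario simulates four bioclim-like variables — warm/cold-quarter
temperature (°C) and wet/dry-quarter precipitation (mm) — as
mean + scale × (0.3 · gradient + 0.954 · latent), where the gradient is a
fixed linear surface (N–S for temperatures, E–W for precipitation) and
the latents are smoothed Gaussian fields (85% low-frequency, 15% white
noise). Because smooth fields carry few effective degrees of freedom,
their sample correlations scatter widely; the latents are therefore
whitened against their realized covariance and residualized against both
gradient surfaces before being colored with the target correlation
matrix, so the realized pairwise inter-variable correlation lands within
±0.09 of the target deterministically (default target 0.3, safely below
the 0.7 collinearity threshold). Slice k (k kyr BP) shifts each variable
mean by k × drift; default drift is glacial-style cooling/drying
(−0.25 °C and −0.3 °C per kyr for the temperature quarters, −12 and
−2.5 mm per kyr for precipitation). Precipitation is clipped at 0 after
drifting; where the clip binds, the per-slice mean shift is legitimately
sub-linear (the exact-linearity property holds only while the clip is
inactive).

Virtual species have Gaussian niches: suitability = max_suitability ×
exp(−½ Σ ((env−center)/width)²). Occurrences are sampled without
replacement at cell resolution with probability proportional to true
suitability at the present slice (cleaning deduplicates per cell anyway);
the default 100 occurrences per species mirrors typical single-species
compilations of a few dozen to a few hundred records. Fossils are planted
at cells with true suitability ≥ 50% of maximum at the target slice,
optionally < 10% of maximum today ("outside the current range"), with a
±100-yr age interval mimicking calibrated-date brackets. The adversarial
counterpart (`plant_decoy_fossil`) picks a cell whose true suitability
never exceeds 0.1% of maximum at any slice *and* whose climate at the
target slice lies within the present-day range of every variable: a decoy
in non-analogue climate would test clamping artefacts rather than the
species' tolerance, and a decoy at a few percent of maximum suitability
is operationally indistinguishable from a species' weakest occupied cell
under the `S ≥ m` rule.

The bundled four-species scenario separates the species on the two
narrow-tolerance axes (temperature of the warmest quarter, precipitation
of the wettest quarter) with centre separations of at least twice the sum
of the paired widths, on a 50×50 grid with 13 slices and strengthened
drift (−0.45 °C, −20 mm per kyr on the separating axes) so that a fossil
planted at 10 kyr BP for the cool-dry species falls outside its current
range. The two-species variant (40×40, 11 slices) backs the worked
example and the end-to-end determinism check.

## What the synthetic tests do and do not show

The generator emulates the *structure* of real inputs — correlated smooth
climate fields, 1-kyr drift, niche-driven occurrence records, dated
fossils — but not their failure modes: no sampling bias or spatial
clustering of records, no georeferencing error, no dating uncertainty
beyond the fixed ±100-yr bracket, no paleoclimate reconstruction error,
no land/ocean geometry, and niches that are exactly Gaussian and exactly
conserved. Passing tests therefore demonstrate that the pipeline recovers
truth when its assumptions hold, not that any real fossil assignment is
correct; on real data the MESS/clamping caveats and the cross-algorithm
consensus carry the weight that ground truth carries here.

## Numerical and design choices

- Coordinates are WGS84 decimal degrees, lon/lat order; a point belongs
  to the half-open cell containing it, grids originate at the north-west
  corner. Occurrence deduplication is at cell resolution.
- Collinearity elimination is greedy: repeatedly take the worst pair at
  or above the threshold and drop the member with the larger mean
  absolute correlation to the remaining set (ties keep the
  earlier-listed variable). Constant variables are dropped first with a
  warning (undefined correlation).
- The pseudo-absence count for GLM/RF defaults to 1000, mirroring the
  Maxent background size; neither choice is sacred and both are config
  fields.
- All randomness flows through explicit integer seeds; the pipeline
  derives stage seeds from the single run seed via `SeedSequence`, and
  the manifest's per-file sha256 checksums make end-to-end determinism
  checkable.
- Problem sizes in the test suite and acceptance script (grids of
  40×40–60×60 cells, 100–500 presences, 20 replicates) were chosen as
  the smallest at which the statistical contrasts of interest are
  clearly resolved.
- Model JSON documents are versioned. Maxent/GLM serialize their fitted
  weights; the random forest serializes its (small) training table plus
  settings and seed and is refitted identically on load — trading load
  time for a portable text format.

## Known limitations

- The `S ≥ m` rule is permissive: `m` is a minimum over occurrence
  points, so a single marginal record lowers the bar for every candidate.
  The per-candidate `S/m` ratio and the full evidence table are reported
  so stricter readings are recoverable.
- Maxent's logistic output is a monotone transform of the fitted density,
  not a calibrated probability; comparisons across species (the ranking)
  inherit this caveat, which is one reason the validation step exists.
- Clamped hindcasts saturate rather than extrapolate; in strongly
  non-analogue climate the assignment's MESS caveat, not the suitability
  number, is the informative output.
- No spatially structured cross-validation; with spatially autocorrelated
  real records the reported AUC/TSS will be optimistic.
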