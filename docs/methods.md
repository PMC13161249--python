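# Methods

This note records the statistical model behind `ildselect`, the defaults
and why they were chosen, what the synthetic generator does and does not
emulate, and the numerical decisions that affect reproducibility.

## Superimposition and symmetrization

Configurations are aligned by generalized Procrustes analysis with
rotation-only orthogonal fits (determinant +1 enforced by sign-flipping
the smallest singular value, so reflections can never leak into the
alignment). By default no scaling is applied: the result is a *form
space* in which every configuration keeps its original centroid size and
therefore all interlandmark distances keep their millimetre values
exactly (preserved to < 1e-9 mm, verified by tests). With `scale=True`
configurations are rescaled to unit centroid size first (shape space);
the form-space route is the one the rest of the pipeline assumes.

Iteration alternates rotating each configuration to the running consensus
with replacing the consensus by the mean. Two numerical choices matter:

* the consensus frame is re-anchored to the first individual's centred
  configuration at every iteration. Without this the mean drifts
  rotationally, which both stalls the convergence criterion and leaves
  the output orientation arbitrary; with it the output is deterministic.
* convergence is declared when the RMS consensus change falls below
  1e-10 mm, with a 1000-iteration cap and an error (never a silent
  return) on failure. The cap is generous because alternating GPA is
  only linearly convergent on very dispersed shape samples; realistic
  morphometric samples converge in a handful of iterations.

The symmetric component of a configuration is the average of the
configuration and its reflected-and-relabelled copy (first coordinate
axis negated — any fixed axis is equivalent up to rotation — and
left/right labels swapped) after rigidly re-aligning the copy. The
mirror-align-average step is iterated to its fixed point (changes below
1e-13 mm), which makes the output *exactly* invariant under
reflect-and-relabel rather than invariant only to first order; the
symmetrized set then re-enters the no-scaling GPA. Symmetrize is
idempotent and makes every mirror-image ILD pair numerically identical
(< 1e-8 mm), which is what licenses dropping one of each pair.

## ILD enumeration and redundancy

All q(q−1)/2 unordered pairs are enumerated in lexicographic index order.
Redundancy is identified *structurally* from the symmetry map, not
numerically: the mirror of pair {a, b} is {σ(a), σ(b)} with σ the
left/right swap; when the mirrored pair differs, the lexicographically
smaller pair is the canonical representative. This works on raw
(unsymmetrized) coordinates too, where the mirror columns are merely
nearly rather than exactly equal. Names drop side markers (sides are
interchangeable after symmetrization) and add an `-ss` suffix when both
landmarks of a bilateral pair lie on the same side, distinguishing e.g.
same-side from cross-midline nasomaxillary–zygion.

Scoring runs over all columns by default (canonical-only is available as
an option) and the reported top set is deduplicated to canonical names
afterwards, mirroring the two-stage handling of redundant columns: a
percentile over the full 465 columns, a report over the 249 canonical
ILDs.

## Association scores and the top set

For a two-level factor the score of an ILD is the between-group over
total sum of squares, identical to the R² of a one-predictor linear
model on the group indicator (verified against a least-squares oracle to
1e-12); for a covariate it is the squared Pearson correlation, with
whole-row resampling in the bootstrap. Constant columns score 0 and are
flagged degenerate instead of producing NaN, keeping the ranking total;
"constant" uses a relative floor (1e-9 of the column mean) so that the
rounding jitter of summing identical floats cannot manufacture spurious
variance.

The top set has k = ⌈(1 − r2tol)·M⌉ members — the only reading of an
upper-percentile rule under which 465 scores at r2tol = 0.98 yield a
"top ten" (9.3 → 10). The product is rounded at 1e-9 before the ceiling
so that exact boundaries (2% of 100) are not inflated by binary float
representation. Ranking resolves scores at 1e-12 and breaks ties by ILD
name, then column index: selection is deterministic, including under
bootstrap resampling where exact ties (R² = 1) would otherwise flip on
the last bit of a sum.

Bootstrap support resamples each group independently with replacement at
its own size; a top ILD counts as re-selected when any column of its
mirror class enters that round's own top-k. Support is
(1 + hits)/(wg_rounds + 1): with 99 rounds the denominator is 100 and
supports are round percentages. One root seed spawns an independent
substream per round, so results are bit-reproducible and independent of
evaluation order. `wg_rounds=0` is legal (supports 1/1) and warns.

## Subsampling experiment

Each of `n_reps` replicates draws `n_per_group` individuals per group
without replacement and reruns the full selection; replicates are
independent draws and therefore overlap. An ILD is recorded for a
replicate when its bootstrap support is **at least** the support
threshold (≥ 0.5), and enters the final predictor set when recorded in
**strictly more than** the frequency threshold (> 0.5) of replicates —
the two different inequalities are deliberate and tracked separately.
Aggregation keys are canonical ILD names, so left/right duplicates can
never double-count. Per ILD the summary reports the supporting-replicate
count and frequency plus median/min/max of both the bootstrap support
and the observed R² across supporting replicates only.

## Classification

The discriminant model is the standard equal-covariance Gaussian: group
means, pooled within-group covariance with divisor n − 2, priors equal by
default (the forensic convention; with balanced groups equal and
proportional priors coincide, and both are available). Posteriors come
from Mahalanobis distances in log-space for numerical safety. Leave-one-
out cross-validation refits means *and* covariance for every left-out
case — exactness was preferred over a downdate shortcut at n ≈ 200.
A case with posterior exactly 0.5 is labelled indeterminate and counted
against its true group in the confusion table (conservative reporting).
The report gives per-group accuracies, their mean, and the signed bias
(first-group minus second-group accuracy, e.g. 92 and 87 → +5).

Typicality of a case in a group is the upper-tail chi-squared probability
(p degrees of freedom) of its squared Mahalanobis distance — the
probability-integral-transform property (uniform typicality for cases
drawn from the fitted Gaussian) is verified by a KS test. A small-sample
F-based variant would differ slightly at these sizes; the chi-squared
definition is the standard one and is what the tests pin down.

## Thin-plate-spline contour surface

The surface solves the standard 2D thin-plate system: kernel
K(r) = r²·log r on the training points, affine part (1, x, y), side
conditions Pᵀw = 0, and a ridge term λ on the kernel block. λ = 0 gives
exact interpolation (reproduces training values to 1e-8 and affine
functions exactly); λ = "gcv" (the default, matching common smoothing
practice) minimizes n·RSS/(n − tr A)² over a fixed logarithmic grid
(10⁻⁸…10⁴, 25 points; ties to the smaller λ), which is deterministic and
reproducible. Duplicate training points are refused — with conflicting
values the problem is ill-posed, and even with equal values the λ = 0
system is singular, so the error advises λ > 0. The 1/(8π) kernel
constant is absorbed into the weights; it cannot affect the fitted
surface.

Grids default to 200×200 over the data range padded by 5%. Interpolated
PPs are clamped to [0, 1] for display and classification (a TPS can
overshoot; probabilities cannot), with the raw surface retained for
audit. Contour levels are fixed at 0.0–1.0 in 0.1 steps, the 0.5
decision isoline emphasized and 0.2/0.8 highlighted as the two groups'
80%-confidence boundaries. Classification of new cases reports the
clamped PP, the predicted label (indeterminate exactly at the
threshold), the 0.1-wide PP band, a low-confidence flag when the
group-specific PP is below 0.8, and an extrapolation flag for points
outside the convex hull of the training data — extrapolated readings are
never hidden, because the characteristic failure mode of transferring a
contour chart to a different population is precisely that the new cases
fall outside the training cloud. The plot refuses more than two
predictors: the contour scatterplot only exists in a two-ILD data space.

## Synthetic data

The generator emulates a craniometric study design: m midplane landmarks
on the x = 0 plane plus p mirror-exact bilateral pairs (defaults 7 + 12 =
31, with anatomical names), two groups of `n_per_group` individuals
(default 100 + 100, females first), i.i.d. isotropic Gaussian coordinate
noise (default 2 mm, giving within-group ILD coefficients of variation
of a few percent at cranial scale), optional antisymmetric jitter, and
dimorphism planted in *landmark* space: a uniform size ratio of the
target-group mean and/or explicit mean displacements of chosen
landmarks, applied mirror-symmetrically to bilateral pairs. ILD-level
truth is derived from the two noise-free mean configurations, the way
real dimorphism propagates into distances. Everything is bit-reproducible
from the seed.

What the generator does **not** emulate: realistic cranial shape,
allometry, correlated digitizing error, or measurement error growing
with (or proportionally larger in) small distances. Passing tests
therefore demonstrate the statistical machinery — scoring, resampling
bookkeeping, selection, classification, interpolation — not the
biological realism of any particular dataset.

`expected_rsq` gives the exact finite-n mean of the two-group sample R²
via the noncentral-Beta Poisson mixture (SSB/σ² ~ χ²₁(λ) with
λ = n₁n₂Δ²/(nσ²), independent of SSW/σ² ~ χ²ₙ₋₂), normalized over the
summed Poisson weights for stability at large λ. It reduces to 1/(n−1)
at Δ = 0 and is validated against brute-force Monte-Carlo before any
test relies on it.

### The two-probe fixture

Recovery tests need a dataset in which exactly two ILDs are dimorphic.
That cannot be arranged with generic geometry: displacing a landmark
perturbs all q − 1 of its distances at first order. The probe fixture
solves this exactly by construction: every landmark except one off-plane
partner (glabella, 50 mm below the plane) lies on z = 0, and the
dimorphism displaces nasion and lambda along z. Each non-displaced
landmark then sits on (or within second order of) the perpendicular
bisector plane of the displacement, so non-planted ILDs change by only
δ²/2L — a few tenths of a millimetre — while nasion–glabella and
glabella–lambda shift by a calibrated full δ. Displacements are sized so
each planted ILD has standardized separation exactly d (ILD noise SD is
√2·σ along the axis; the oblique glabella–lambda displacement is solved
exactly), with σ = 1 mm keeping the second-order background an order of
magnitude below the planted signal. Because both planted ILDs share the
glabella endpoint their noise is positively correlated
(cov = σ²·ê₁·ê₂); the fixture returns the analytic mean-difference
vector and 2×2 covariance, from which the two-Gaussian Bayes accuracy
Φ(√(δᵀΣ⁻¹δ)/2) is computed for classifier calibration checks. This is a
designed test instrument, not a realistic cranium, and is documented as
such.

## Problem sizes used in the test suite

The recovery experiment runs at the full design scale of the study it
models — 31 landmarks, 100 + 100 individuals, balanced 50 + 50
subsamples, 99 bootstrap rounds, top 2% — with 25 subsample replicates
per master seed and 10 master seeds, sizes chosen to estimate the
recovery proportion with adequate resolution while keeping the default
test run in the low minutes. Monte-Carlo validations use 10⁵ replicates
(R² expectation) and 10⁴ samples (typicality PIT).

## Known limitations

* Only two-level factors or a single covariate; multi-group factors and
  multiple covariates are out of scope.
* No missing-landmark handling, semilandmarks, or tangent-space
  projection; no Morphologika/NTS readers.
* The TPS file format cannot carry landmark names; round trips through
  TPS preserve coordinates and individual ids, with names regenerated.
* Stepwise discriminant predictor selection and >2-predictor contour
  visualizations (between-group PC planes) are deliberately not
  implemented.
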