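# Methods

## Problem setting

`popmarker` analyses *agent-based models of heterogeneous cell
populations*: ensembles of N independent single cells, each governed by
the same deterministic ODE model

    dx/dt = f(x, θ),    x(0) = x0(θ),

but with its own parameter vector θ drawn from a population density.
Because each cell's response is a deterministic function of its
parameters, any scalar property of the trajectory — a binary fate label
δ(θ) ∈ {−1, +1} or a positive event time φ(θ) — becomes a function of θ,
and the question "which cellular quantities drive the heterogeneity of
the response?" becomes a supervised-learning question on simulated
(θ, δ) and (θ, φ) samples.  The package implements the full loop:
sampling, simulation, labelling, parallel-coordinates visualization for
hypothesis generation, and support-vector scoring of candidate marker
subsets for quantification.

## Population model and sampling

Extrinsic variability is modelled by independent log-normal marginals,
one per heterogeneous parameter, specified by a location (mean or median,
in model units) and a coefficient of variation.  The log-scale parameters
follow from

    σ² = ln(1 + CV²),   μ = ln(median)  or  μ = ln(mean) − σ²/2.

Independence is an explicit assumption: only marginals are specified, and
correlated sampling (copulas) is out of scope.  `cv = 0` denotes a point
mass, so fixed and heterogeneous parameters can be treated uniformly.

Sampling consumes a single generator stream column by column.  The
practical consequence, which is tested: appending a new heterogeneous
parameter to a specification does not change the draws of the existing
columns at the same seed.  Sampling is a pure function of
(specs, N, seed).

## Ensemble simulation

Each cell is an independent initial-value problem, integrated with LSODA
(stiff/non-stiff switching) because switch-like signalling models produce
sharp transients; the bundled caspase model supplies a compiled
right-hand side and analytic Jacobian for throughput (~2–3 ms per cell at
the default tolerances).  Defaults: relative tolerance 1e-8, absolute
tolerance 1e-10 in copy-number units, output grid of 721 points over 12 h
(1-minute resolution).  These are engineering choices validated by
self-convergence (tightening tolerances moves endpoints by less than 10×
the looser tolerance) and by the dense-grid event-timing check below.

A failed integration aborts the ensemble by default — silently dropping
cells would bias every downstream statistic; a permissive mode records
failed row indices and fills them with NaN instead.

Steady states are computed with a Newton-type root finder on a reduced
system in which designated states are clamped (typically the active
species at zero, giving the pre-stimulation "resting" state); the result
is cross-checked in tests against closed forms and long-time simulation.

## Decision and timing functionals

The qualitative property is threshold exceedance of one species within an
observation window: +1 if max_t x_j(t) ≥ x_th (ties count as crossing),
−1 otherwise.  The quantitative property is the earliest crossing time,
defined only for crossing cells.  Both are evaluated on the solver output
grid and refined: grid crossings are bracketed and polished with a local
cubic spline root; maxima that only touch the threshold between grid
points are caught by polishing interior local maxima.  The refined times
agree with a 100×-denser brute-force grid scan to better than 1e-3 h on
the caspase model (tested).

Two labelling conventions are supported, because the natural positive
class depends on the application: `crossing_positive` (the functional
itself) and `survival_positive` (flipped; non-crossing cells are +1).
The caspase case study uses `survival_positive` — the positive class is
survival, and all TP/FP figures refer to survival classification.

A configurable constant `death_offset` (minutes) can be added to crossing
times for processes where commitment is declared a fixed delay after the
molecular threshold; it defaults to 0 because a constant offset shifts
all event times equally and cannot change which markers predict timing.

## Marker scoring

A marker set m is scored by training a kernel machine restricted to the
columns θ_m:

* fate: soft-margin support-vector classification (RBF kernel),
  `sign(w·Φ(θ_m) + b)`;
* timing: ε-insensitive support-vector regression.

Defaults are γ = 0.25, C = 1, ε = 0.01, natural-log transform of the
features, no standardization (a `standardize` switch exists, off by
default).  The underlying solver is LIBSVM (via scikit-learn).  Scoring
is always on held-out rows: TP = fraction of positive test rows predicted
positive, FP = fraction of negative test rows predicted positive, the ROC
is traced by sweeping a threshold on the continuous decision value of the
single trained classifier, and AUC is its trapezoidal area.  Regression
is summarized by quantiles (median, quartiles, 10th/90th percentiles,
mean) of |relative error| |(φ − φ̂)/φ|; signed errors are retained for
diagnostics.  Rows with φ = 0 cannot be scored relatively and are
excluded with a logged count.

`evaluate_combinations` scores every subset of the requested sizes on one
shared train/test split, sorts by AUC (ties broken lexicographically) and
refuses more than 10⁴ subsets without an explicit override — exhaustive
search over large parameter sets is exactly what the visual pre-selection
step is meant to avoid.

## Parallel coordinates

A q-dimensional parameter vector becomes a polyline over q parallel axes,
each normalized to [0, 1] by its sample range (stored, hence invertible;
optional log axes).  Density is conveyed by translucent overplotting with
per-line opacity α (default 0.03): saturated regions are dense, dark
regions are class overlap.  The draw order is shuffled with a fixed seed
so no class systematically overpaints the other.  For quantitative
responses either a colormap on the polylines or a split into percentile
classes (default 0–10, 45–55, 90–100) with a mean-polyline overlay is
available.  Rendering is static (matplotlib); interactivity is a
non-goal.  Assertions about figures in tests are numerical (class-median
gaps, subset means on normalized axes), never pixel comparisons.

## The caspase case study

The bundled application is the classic bistable caspase cascade: C8a
activates C3; C3a feeds back onto C8; IAP binds C3a (and is co-degraded),
CARP binds C8a; all eight species undergo first-order turnover.  With
zero active caspases the turnover equations decouple, so the resting
state is exactly synthesis/degradation per protein (C8 1.3e5, C3 2.1e4,
IAP 4e4, CARP 4e4 copies for the nominal cell) — each cell starts from
*its own* resting state plus its sampled stimulus C8a(0).  Death is
declared when free C3a reaches 5,000 copies within 12 h.

Heterogeneity: the four synthesis rates km8 (IAP), km9 (C8), km10 (C3),
km12 (CARP) are log-normal with mean at the published constants and
CV 0.4; the stimulus C8a(0) is log-normal with median 4,000 molecules and
CV 0.4.

### Kinetic constants

The rate constants live in `src/popmarker/data/caspase_constants.yaml`
(molecules and minutes; the simulation interface is hours).  They are a
transcription from the original single-cell model publication, which the
package does not vendor; the assignment of the two activation constants
and of the first-order degradation constants to reactions was fixed by
requiring that the transcription reproduce the published behaviour of the
model at both levels:

* single cell: the unstimulated resting state is stable, and the nominal
  cell is switched to apoptosis by an initial C8a dose of a few thousand
  molecules (its switching threshold here is ≈2.7e3);
* population: the survival-classification AUC table is reproduced within
  a few hundredths for most entries, with (km8, km10) the best pair, and
  death-time regression medians for marker pairs in the 35–45% range.

Residual quantitative discrepancies and their interpretation are
discussed under "Known limitations".

### Case-study workflow

`run_case_study` simulates disjoint training and test ensembles (seeds
derived from one master seed via a seed sequence), labels them
survival-positive, evaluates all 5 single markers and 10 pairs
(classification and regression) on the shared split, and evaluates the
three triplets extending the best pair.  Problem sizes default to 10,000
training and 10,000 test cells — large enough that AUC standard errors
are ≈0.005.

## Synthetic benchmark

The linear-threshold benchmark generates i.i.d. log-normal parameters; the
label is +1 exactly when a designated parameter exceeds its distribution
median (a balanced split in expectation), and the event time of positive
rows is `timescale · (median/θ_inf)` with 5% multiplicative log-normal
noise — a smooth, strictly decreasing function of the informative
parameter.  Because the ground truth is known by construction, marker
scoring must give AUC → 1 for the informative parameter and chance level
for all others; this is the package's core self-test and is independent
of the caspase transcription.  Default dimensionality is q = 3 (one
informative, two decoys), which keeps the property sharp while the
training cost of the deliberately uninformative (label-noise) fits stays
moderate.

What the benchmark does *not* emulate: correlated parameters, label noise
at the decision boundary, multi-parameter decision surfaces, or dynamics
(it bypasses the ODE layer entirely).  Passing it shows the scoring
machinery recovers planted structure, not that any particular biological
model is transcribed correctly — the case-study checks carry that weight.

## Numerical and design choices

* Event polishing uses local cubic splines (4–5 support points) with
  Brent root finding; a linear-interpolation fallback covers kinks where
  the spline disagrees with the grid bracket.
* Cells crossing exactly at the horizon are included in the timing
  sample; later crossings are unobserved by construction.
* ROC curves are prepended/appended with (0,0) and (1,1); AUC is
  trapezoidal; the native TP/FP point (decision value 0) lies on the
  curve by construction (tested to machine precision).
* Class imbalance is not reweighted (library defaults), matching the
  stated support-vector settings; the imbalance is logged.
* Three named seeds (sampling, split, rendering order) are logged by the
  pipeline so any artifact is reproducible from its config file alone.
* Constant parallel-coordinate axes (zero range) are pinned to 0.5 with a
  warning rather than rejected.

## Known limitations

* The kinetic-constant file is a transcription; the population-level
  reproduction is quantitative but not exact.  At the default study
  conditions the death fraction is ≈0.54, the best-pair survival AUC is
  ≈0.865, and the native-threshold TP/FP operating points of weak markers
  sit at a more conservative position on the ROC curves than the
  originally reported ones, which resemble a more balanced-class
  operating point; the AUC gap between the best pair (km8, km10) and the
  runner-up (km10, km12) is narrow (≈0.005–0.01), making the strict pair
  ranking sensitive to the sampling seed.  Threshold-free quantities (AUC
  ordering by marker family, regression medians ≈0.34–0.42 for pairs,
  qualitative axis separations) reproduce well.  Feature scaling after
  the log transform (z-scoring or min–max) was checked and does not close
  the gap.
* Only log-normal marginals are implemented; no copulas/correlations, no
  distribution fitting from data.
* The single-cell model class is deterministic ODEs; stochastic single
  cell models are out of scope.
* Exhaustive subset search is guarded, not optimized; the intended use is
  visual pre-selection followed by scoring of a handful of candidates.
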