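# Methods

This note documents the models, conventions, and calibration choices behind
`vestenc`, in the spirit of a methods appendix: what is computed, under
which assumptions, with which defaults, and what the synthetic test bed does
and does not establish about real recordings.

## Signals and conventions

All channels live on a uniform grid (default 1 kHz).  Pitch angular
velocity is in deg/s; net gravito-inertial acceleration in g along the
afferent's preferred axis.  Derived channels (angular acceleration, jerk)
use one shared convention everywhere — zero-phase Butterworth smoothing at
125 Hz followed by central differences — so a ground-truth afferent built
from a trace's derived channel and an analysis of that same trace agree
exactly.  A *positive response lead* means firing precedes motion; it is
applied by advancing the stimulus (edge-hold padding).

## Synthetic head-motion conditions

The generator defines six conditions.  The two sinusoidal characterization
protocols are exact: 1 Hz, ±0.2 g translation, and 1 Hz, 40 deg/s pitch
with a ±0.2 g gravito-inertial component in quadrature (the acceleration
follows head position, 90° behind velocity).

The four naturalistic conditions form two statistically matched pairs
(walking / walking-matched passive, running / running-matched passive),
defined by their amplitude statistics relative to the walking-matched
passive reference: the fraction of samples beyond ±1.5 SD of that
reference.  Defaults (net acceleration: 15 % running, 5 % walking, 3 %
passive; rotational velocity: 4 % running, 2 % walking, 3 % passive) are
the study conditions the generator is built to emulate.

Two generative families realize those targets:

* **Quasi-periodic** (walking-like and passive channels, and running
  rotation): x(t) = A·sin θ(t) + s·g(t), where θ drifts slowly around the
  step rate (band-limited frequency noise, relative SD 5 %, so the process
  and its derivatives keep their power near the fundamental) and g is
  unit-variance Gaussian noise low-passed at 4 Hz (8 Hz for running).
  With a uniform initial phase the marginal is exactly an arcsine ⊕
  Gaussian convolution, so the tail probability at any threshold is a 1-D
  quadrature over phase.  The periodic share r (A = √2·r·SD,
  s = √(1−r²)·SD) is root-found against the target *before any sampling*.
  Light tails (2–5 % at 1.5 SD, versus 13.4 % for any Gaussian process)
  force r ≈ 0.99: the conditions are strongly oscillatory, which is also
  what makes such sub-Gaussian tail percentages possible at all.
* **Two-component Gaussian scale mixture** (running / running-matched
  passive acceleration): a low-scale "body" process with occasional
  high-scale bursts, switched by a thresholded slow (1.5 Hz) Gaussian
  process independent of both carriers, so the stationary marginal is
  exactly the mixture.  With total SD fixed at 1.8× the walking reference
  and body weight 0.88, the body scale is solved in closed form so the
  tail at 1.5 reference SDs equals 15 %.  The resulting kurtosis (~17) and
  SD ordering reproduce the heavier, more impulsive character of running
  head motion.

Running rotational velocity keeps the quasi-periodic family at a faster
step rate (3.2 vs 2.0 Hz) and only 5 % higher SD: a larger SD increase is
mathematically incompatible with a 4 % tail at 1.5 reference SDs (the peak
of any sinusoidal process sits at √2 ≈ 1.41 SD), so the extra running power
is placed at higher frequencies rather than in amplitude.  Consistently,
the rotational amplitude distributions barely differ across conditions
while the normalized cumulative spectrum of running has a smaller area.

A static head-pitch tilt (default 15°, identical across conditions) defines
the gravity-including forward/vertical accelerometer axes used for mean
head-orientation estimates.

What the generator does **not** emulate: gait biomechanics, 3-D rotations,
coupling between rotational and linear channels, nonstationary bout
structure, or sensor noise.  Passing tests therefore demonstrate
correctness of the analysis chain under known ground truth with realistic
amplitude/spectral statistics — not that real recordings satisfy these
generative forms.

## Simulated afferents

A ground-truth afferent is a linear stage — resting rate plus organ
coefficients applied to the lead-advanced stimulus — passed through a
static nonlinearity, then spiked.  Two nonlinearities are available:
rectification at zero ("linear-rectified"), and the erf sigmoid
Tsig(x) = (c3/2)[1 + erf((x − c2)/√(2c1))].

Ground-truth sigmoids are constructed by the **unit-gain resting
convention**: Tsig passes through (r0, r0) with slope 1, leaving only the
ceiling ratio c3/r0 free (default range 3–5).  Two reasons.  First, an LN
model is only identified up to the scale split between linear gain and
sigmoid input: any (St, c1, c2) can be rescaled jointly without changing
the input–output map.  The fitting procedure pins that scale through the
linear-range regression, and a truth built in the same convention makes
"parameter recovery" well-posed.  Second, it is the natural physiological
statement: near rest the sigmoid passes the linear drive through unchanged
and contributes only the cutoff and saturation bends.

Spiking is an inhomogeneous gamma renewal process via time rescaling:
in operational time Λ(t) = ∫r dt the train is ordinary renewal with
Gamma(κ, 1/κ) intervals, so expected counts equal ∫r dt on all timescales
and the resting interspike CV is 1/√κ.  Class defaults: κ = 100 for
regular (CV* ≈ 0.10) and κ = 4 for irregular afferents (CV* ≈ 0.50),
straddling the 0.15 cutoff with wide margins.

Default class parameters (all configurable) place the cohort in the
qualitative regimes of interest: regular classes and canal afferents stay
linear in every condition; irregular otolith afferents (gain 350–450
(sp/s)/g against resting rates of 60–90 sp/s) are driven into inhibitory
cutoff by the running bursts while remaining quasi-linear in the walking
conditions.  Linear-class afferents carry their response dynamics in the
derivative coefficient with zero pure lead — under narrowband stimulation
a time shift and a rotation of the (velocity, acceleration) or
(acceleration, jerk) pair are interchangeable, so "lead" and derivative
sensitivity are two descriptions of the same phase and the package
standardizes on the latter for two-channel models.  Sigmoid-class truths
keep an explicit lead (8–15 ms), which the single-channel LN fit estimates
by cross-correlation.

The default cohort is a within-afferent design: 15/17 regular/irregular
canal and 9/14 regular/irregular otolith afferents, each simulated with
identical ground truth in every condition plus a stimulus-free resting
recording; the drawn regularity class is verified against the measured CV*
during construction.

## Rate estimation and discharge statistics

Firing rates are estimated by binning the spike train at the grid
resolution and convolving with a **Kaiser window used directly as the
smoothing kernel** (not a windowed sinc): the kernel is non-negative and
unit-area, so the rate estimate is non-negative and integrates to the
spike count, and its side lobes sit below −60 dB (β ≈ 5.65).  The window
length is solved numerically so the kernel's −6 dB point falls at the
configured cutoff (default 25 Hz — comfortably above locomotor head-motion
content at 1 kHz sampling; the kernel is then 41 ms long).  The resolution
trade-off matters below ~25 sp/s, where inter-spike gaps exceed the kernel
and the estimate dips toward zero between spikes.

Regularity: CV = SD/mean of resting interspike intervals; CV* refers CV to
a standard mean interval of 15 ms through a power-law normalization curve.
For gamma-renewal discharges CV is independent of the mean interval, so
the package's own calibration of that curve (`calibrate_cv_normalization`)
yields exponent ≈ 0 and CV* = CV by default; the exponent is configurable
for data whose regularity does covary with rate.  CV* ≥ 0.15 classifies
irregular (ties to irregular, for determinism).  A configured minimum of
500 resting intervals guards the estimate.

Modulation is the mean over complete stimulation cycles of the
peak-to-peak rate within the cycle (cycles cut at the condition's
fundamental, or at explicit markers); note this extreme-value statistic is
inflated by estimation noise, which is one reason the model-based St is
preferred for comparisons.  The zero-rate (cutoff) probability is the
fraction of samples at or below ε = 0.5 sp/s, absorbing smoothing leakage
around truly silent epochs; irregular discharges at moderate rates carry a
~1 % noise floor from spiking gaps.

## Linear rate models

Ordinary least squares of the rate on the organ's two motion channels plus
intercept, restricted to samples above 10 sp/s so cutoff-prone epochs do
not bias the fit.  Two refinements, both configurable:

* **Mask on the prediction** (default): truncating on the *noisy measured*
  rate preferentially removes samples with negative estimation noise and
  attenuates coefficients (selection on the dependent variable); the
  package therefore refines the >10 sp/s mask on the fitted model's
  prediction (two to three passes from an observed-rate start), which is
  selection on the regressors only and leaves OLS unbiased, while still
  excluding genuinely cutoff-prone epochs.  `mask_on="observed"`
  reproduces the literal rule.
* **Matched design smoothing** (opt-in): when the rate came from the
  Kaiser estimator, low-passing the regressors with the same kernel puts
  identical filtering on both sides of the regression and removes the
  residual droop bias on derivative channels.

Diagnostics: VAF = 1 − var(residual)/var(observed); VIF per regressor
(values above 10 raise a multicollinearity error; for these stimuli
velocity/acceleration are near-quadrature, VIF ≈ 1); a residual-versus-fit
slope is reported.  The gain formula St(f) = √(S₁² + (2πf·S₂)²) converts a
coefficient pair to the response modulation at a stimulus frequency.

## LN cascade fitting

Stages, in order: (1) response lead from the cross-correlation peak of
rate against the organ's primary channel within ±50 ms (for two-channel
designs the same routine maximizes joint OLS R², the multi-regressor
generalization); (2) linear range = samples with the aligned stimulus
within mean ± 1 SD; (3) least squares of rate on the aligned channel over
that range gives (St, r0); (4) firing rate averaged within 0.0004 g
stimulus bins (canal channels default to SD/50 in deg/s, preserving
comparable occupancy), with edges on integer multiples of the width;
(5) erf sigmoid fitted to the binned means, expressed against the linear
prediction and weighted by bin counts.  Sigmoid initialization:
c3 = maximum binned rate, c2 = half-maximum crossing, c1 = (range/4)²;
bounds keep c1, c3 positive; deterministic single-start trust-region
least squares (tolerances 1e−8).

Reported quantities: bias = Tsig(r0) and modulation = St·T′sig(r0), both
evaluated at the zero-head-motion operating point so they are
unit-commensurate with the linear model's intercept and gain (the
inflection-slope alternative can be read off the fitted parameters
directly); VAF of the LN prediction and of the raw linear prediction on
the full record.  The LN prediction is bounded in [0, c3] by construction.

Because of the gain/width degeneracy discussed above, recovered (St, c1,
c2) should be compared with ground truth in the fitting convention; the
invariants (c1/St², (c2 − r0)/St, bias, modulation, c3, lead, r0) are
convention-free.

## Stimulus statistics

PSDs use Welch averaged modified periodograms (2 s Hann windows, 50 %
overlap) and integrate to the channel variance (Parseval check in tests).
The cumulative spectrum is normalized to end at 1 and its area taken over
0–15 Hz: power shifted toward higher frequencies shrinks the area, which
is how the running condition separates from walking even at similar total
rotational power.  Amplitude summaries report SD and **non-excess**
(Pearson) kurtosis (Gaussian = 3).  The tail fraction of a test channel is
measured against the mean ± k·SD band of a reference channel (default
k = 1.5).  Mean head orientation is the time-averaged arctangent of the
0.5 Hz-low-passed forward over vertical acceleration components.

## Pipeline

`run_analysis` executes, per afferent: regularity classification from the
resting recording → rate estimation per condition → cycle/mean-rate/cutoff
statistics → linear fit on the walking-matched passive condition, carried
forward as a prediction (with VAF) to every condition → LN fit per
naturalistic condition.  Group contrasts are delegated to standard
routines: one-way ANOVA across conditions per class and metric
(scipy), and the identity-line regressions of active against passive
metrics with confidence intervals (statsmodels OLS).  Report tables follow
a versioned column schema shipped with the package; runs are deterministic
given the seed, and failures carry afferent/condition context.

## Problem sizes and numerical notes

Calibration quadrature uses 400-node Gauss–Legendre; root finding is
Brent's method to 1e−12.  Band-limited noise is normalized by the filter's
impulse-response noise gain so expected variances are exact.  The
acceptance script and the recovery tests use 300 s records at 1 kHz (the
tail statistics average ten replicates); recovery assertions average a few
spiking realizations of the same record, reflecting estimator accuracy
rather than single-draw sampling noise.  Unit tests run on 10–120 s
records.  Cohort-level tests use reduced class counts and 30–60 s
conditions; the full 55-afferent default cohort is exercised for structure
(counts, conditions, determinism) at short durations.

## Known limitations

* The quasi-periodic family is nearly periodic (r ≈ 0.99); real locomotor
  head motion is richer.  The light tail-percentage targets leave
  little room for broadband Gaussian components, and the package chooses
  to honor the amplitude statistics exactly.
* Lead and derivative sensitivity are not separable for two-channel
  linear models under narrowband stimulation; the package's zero-lead
  convention for linear classes is one valid parametrization, not a
  physiological claim.
* The zero-rate probability measured on estimated rates has a
  rate-and-regularity-dependent noise floor; comparisons should be within
  afferent across conditions, as in the pipeline.
* Group contrasts assume independent afferents and use standard
  parametric tests; no hierarchical modeling.
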