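# vestenc

Vestibular afferent encoding models: linear and linear–nonlinear (LN)
cascade analysis of head-motion–driven spike trains, with a calibrated
synthetic afferent simulator for passive stimulation, walking, and running
conditions.

## The scientific problem

Primary vestibular afferents carry head-motion signals from the inner ear to
the brainstem: semicircular-canal fibers encode angular head velocity,
otolith fibers encode net gravito-inertial (linear) acceleration.  During
quiet passive stimulation their firing is well described by a linear rate
model, and afferents are classically split into *regular* and *irregular*
classes by the normalized coefficient of variation (CV\*) of their resting
interspike intervals (cutoff 0.15).

During vigorous natural movement — running in particular — the
net-acceleration stimulus develops a heavy-tailed amplitude distribution,
and highly sensitive irregular otolith afferents are driven past their
linear range: the firing rate cannot go below 0 sp/s (*inhibitory cutoff*),
which puts a spike of probability at zero firing rate and lifts the
time-averaged rate above the resting discharge.  A naive linear analysis
then reports an apparent "gain change" across behavioral conditions.  An LN
cascade — the same linear stage followed by a static erf-sigmoid — absorbs
the cutoff and saturation and describes the afferent with one
condition-independent code.  This package implements that whole analysis
chain for experimenters and modelers working with spike trains plus
gyroscope/accelerometer head-motion recordings, and ships a ground-truth
simulator so every stage is testable without any recorded data.

## Models

Linear rate models (least squares, restricted to firing > 10 sp/s):

    canal:    fr(t) = b + Sv·Ḣ(t) + Sa·Ḧ(t)        Ḣ deg/s, Ḧ deg/s²
    otolith:  fr(t) = b + Sa·Ḧ(t) + Sj·H⃛(t)        Ḧ g,     H⃛ g/s

with the frequency-resolved response modulation

    St(f) = √(S₁² + (2πf·S₂)²)

LN cascade (per afferent and condition):

    r(t) = St·H(t + lead) + r0
    N(t) = Tsig(r(t)),   Tsig(x) = (c3/2)·[1 + erf((x − c2)/√(2·c1))]

fitted in stages: cross-correlation lag alignment → linear stage over the
mean ± 1 SD stimulus range → firing rate averaged in 0.0004 g stimulus bins
→ sigmoid fit to the binned tuning versus the linear prediction.  The LN
*bias* is N at zero head motion, Tsig(r0), and the LN *modulation* is the
local slope there, St·T′sig(r0).

Spike trains are reduced to rate traces with a non-negative Kaiser-window
smoothing kernel; discharge regularity, cycle-averaged peak-to-peak
modulation, and the zero-rate (cutoff) probability are computed from the
same traces.  The synthetic module generates sinusoidal characterization
stimuli, quasi-periodic walking-like motion, and burst-mixture running-like
motion whose tail statistics are calibrated analytically before sampling,
and simulates all four afferent classes with inhomogeneous gamma-renewal
spiking.  See `docs/methods.md` for the full model description.

## Worked example

Simulate a high-gain irregular otolith afferent during 300 s of running-like
motion, estimate its firing rate, and fit the LN cascade:

```python
from vestenc import (AfferentGroundTruth, SigmoidParams, estimate_firing_rate,
                     fit_ln_model, generate_stimulus, simulate_afferent,
                     zero_rate_probability)

running = generate_stimulus("running", 300.0, seed=7)
sigmoid = SigmoidParams.with_unit_gain_resting(75.0, 225.0)
truth = AfferentGroundTruth(organ="otolith", regularity="irregular",
                            resting_rate=75.0, response_lead_s=0.012,
                            isi_shape=4.0, sa=400.0, sj=0.0,
                            nonlinearity=sigmoid)
rec = simulate_afferent(truth, running, seed=13)
rate = estimate_firing_rate(rec.spike_times, running.t)
ln = fit_ln_model(rate.rate, running.linear_acceleration, 1000.0,
                  organ="otolith")
```

This prints (see the example script under the same seeds):

```
response lead       = 11 ms   (truth 12 ms)
linear stage        : St = 375 (sp/s)/g, r0 = 76.7 sp/s (truth 400, 75)
sigmoid             : c1 = 6380, c2 = 109.4, c3 = 221.0 (truth 6693, 110.2, 225)
bias / modulation   = 75.4 sp/s, 381 (sp/s)/g
VAF                 : LN = 0.61, linear = 0.34
zero-rate dwell     = 0.028
mean rate vs rest   = 78.8 vs 75.0 sp/s
```

Reading the numbers: the recovered linear stage and sigmoid sit within ~10 %
of the simulated ground truth; the LN model roughly doubles the variance
accounted for relative to the raw linear prediction because the afferent
spends ~3 % of the running record in inhibitory cutoff (zero-rate dwell),
which also lifts its mean rate ~4 sp/s above the resting discharge — the
signature that a linear analysis would misread as a gain change.

A command-line surface mirrors the workflow:

```bash
vestenc simulate --out cohort/ --seed 1         # synthetic cohort to CSV/text
vestenc characterize --spikes cohort/spikes/oto_irr_00__rest.txt
vestenc fit-ln --spikes ... --stim cohort/stimuli/running.csv --organ otolith
vestenc compare --out analysis/ --seed 1        # full per-afferent tables
```

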