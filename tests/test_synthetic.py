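"""Synthetic stimulus generator and afferent simulator."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.stats import norm

from vestenc.ln_cascade import SigmoidParams
from vestenc.spike_processing import estimate_firing_rate
from vestenc.stimulus_stats import tail_fraction
from vestenc.synthetic import (
    CONDITIONS,
    AfferentGroundTruth,
    CohortConfig,
    StimulusParams,
    StimulusTrace,
    calibrate_quasiperiodic,
    calibrate_scale_mixture,
    generate_cohort,
    generate_stimulus,
    quasiperiodic_tail,
    scale_mixture_tail,
    simulate_afferent,
)

FS = 1000.0


# ---------------------------------------------------------------- calibration


@pytest.mark.parametrize("target", [0.02, 0.03, 0.05])
def test_quasiperiodic_calibration_is_exact_before_sampling(target):
    r = calibrate_quasiperiodic(target, 1.5)
    assert quasiperiodic_tail(r, 1.5) == pytest.approx(target, abs=1e-9)


def test_scale_mixture_calibration_matches_closed_form():
    s1, s2 = calibrate_scale_mixture(0.15, 1.8, 0.88, 1.5)
    assert scale_mixture_tail(s1, s2, 0.88, 1.5) == pytest.approx(0.15, abs=1e-9)
    # variance constraint: total SD equals the configured ratio
    var = 0.88 * s1**2 + 0.12 * s2**2
    assert np.sqrt(var) == pytest.approx(1.8, rel=1e-9)


def test_unachievable_tail_targets_raise():
    with pytest.raises(ValueError):
        calibrate_quasiperiodic(0.5, 1.5)  # heavier than Gaussian
    with pytest.raises(ValueError):
        calibrate_scale_mixture(0.9, 1.8, 0.88, 1.5)


def test_quasiperiodic_tail_shape():
    """Gaussian limit at r = 0; steeply lighter tails as the periodic share
    approaches 1 (the calibration branch)."""
    assert quasiperiodic_tail(0.0, 1.5) == pytest.approx(2 * norm.sf(1.5), rel=1e-6)
    tails = [quasiperiodic_tail(r, 1.5) for r in (0.9, 0.95, 0.99, 0.999)]
    assert all(a > b for a, b in zip(tails, tails[1:]))
    assert tails[-1] < 0.01


# ------------------------------------------------------------------- stimuli


def test_sinusoid_translation_amplitude(params):
    trace = generate_stimulus("passive_sinusoid_translation", 10.0, params)
    assert np.max(np.abs(trace.linear_acceleration)) == pytest.approx(0.2, rel=1e-3)
    assert np.allclose(trace.pitch_velocity, 0.0)
    # exact 1 Hz sinusoid: 10 zero crossings per 10 s on the upward slope
    crossings = np.sum(np.diff(np.signbit(trace.linear_acceleration)) != 0)
    assert crossings == pytest.approx(20, abs=1)


def test_sinusoid_pitch_velocity_amplitude(params):
    trace = generate_stimulus("passive_sinusoid_pitch", 10.0, params)
    assert np.max(np.abs(trace.pitch_velocity)) == pytest.approx(40.0, rel=1e-3)
    assert np.max(np.abs(trace.linear_acceleration)) == pytest.approx(0.2, rel=1e-3)


def test_zero_amplitude_gives_zero_channels():
    p = StimulusParams(accel_sd_g=0.0, vel_sd_dps=0.0)
    trace = generate_stimulus("walking", 5.0, p, seed=1)
    assert np.allclose(trace.linear_acceleration, 0.0)
    assert np.allclose(trace.pitch_velocity, 0.0)


def test_generate_stimulus_errors(params):
    with pytest.raises(ValueError):
        generate_stimulus("jogging", 10.0, params)
    with pytest.raises(ValueError):
        generate_stimulus("walking", -1.0, params)
    with pytest.raises(ValueError):
        generate_stimulus("walking", 10.0, params)  # stochastic without seed


def test_running_tail_fraction_matches_calibration(running_120s, passive_low_120s):
    frac = tail_fraction(
        running_120s.linear_acceleration, passive_low_120s.linear_acceleration
    )
    # single 120 s record: burst occupancy fluctuates; the tight multi-seed
    # check lives in the acceptance suite
    assert frac == pytest.approx(0.15, abs=0.05)


def test_matched_pair_sd_and_power_ordering(
    passive_low_120s, walking_120s, running_120s
):
    sd_p = passive_low_120s.linear_acceleration.std()
    sd_w = walking_120s.linear_acceleration.std()
    assert sd_w == pytest.approx(sd_p, rel=0.05)
    assert running_120s.linear_acceleration.var() > 2.0 * walking_120s.linear_acceleration.var()
    assert running_120s.pitch_velocity.var() > walking_120s.pitch_velocity.var()


def test_derived_channels_are_derivatives(passive_low_120s):
    tr = passive_low_120s
    dt = 1.0 / tr.sample_rate
    num = np.gradient(tr.pitch_velocity, dt)
    # compare away from edges; shared smoothing leaves band-limited channels intact
    inner = slice(100, -100)
    err = np.abs(tr.pitch_acceleration[inner] - num[inner])
    assert np.percentile(err, 99) < 0.02 * np.abs(num[inner]).max()


def test_trace_validation_rejects_bad_grids():
    with pytest.raises(ValueError):
        StimulusTrace(
            t=np.array([0.0, 0.1, 0.15]),
            pitch_velocity=np.zeros(3),
            linear_acceleration=np.zeros(3),
            condition="walking",
            sample_rate=10.0,
        )
    with pytest.raises(ValueError):
        StimulusTrace(
            t=np.arange(5) / FS,
            pitch_velocity=np.zeros(5),
            linear_acceleration=np.zeros(5),
            condition="jogging",
            sample_rate=FS,
        )


# ------------------------------------------------------------------ afferents


def test_ground_truth_validation():
    with pytest.raises(ValueError):
        AfferentGroundTruth(
            organ="canal", regularity="regular", resting_rate=80.0,
            response_lead_s=0.0, isi_shape=10.0, sa=1.0, sj=1.0,
        )
    with pytest.raises(ValueError):
        AfferentGroundTruth(
            organ="otolith", regularity="regular", resting_rate=-5.0,
            response_lead_s=0.0, isi_shape=10.0, sa=1.0, sj=0.0,
        )
    with pytest.raises(ValueError):
        AfferentGroundTruth(
            organ="otolith", regularity="regular", resting_rate=80.0,
            response_lead_s=0.0, isi_shape=0.5, sa=1.0, sj=0.0,
        )


def test_unmodulated_afferent_fires_at_resting_rate():
    n = int(60 * FS)
    still = StimulusTrace(
        t=np.arange(n) / FS, pitch_velocity=np.zeros(n),
        linear_acceleration=np.zeros(n), condition="passive_low", sample_rate=FS,
    )
    truth = AfferentGroundTruth(
        organ="otolith", regularity="regular", resting_rate=80.0,
        response_lead_s=0.0, isi_shape=100.0, sa=50.0, sj=0.0,
    )
    rec = simulate_afferent(truth, still, seed=7)
    mean_rate = rec.spike_times.size / 60.0
    assert mean_rate == pytest.approx(80.0, rel=0.02)
    isis = np.diff(rec.spike_times)
    assert isis.std() / isis.mean() == pytest.approx(0.1, rel=0.15)


def test_canal_sinusoid_modulation_depth(params):
    """Peak-to-peak rate modulation equals 2 * Sv * velocity amplitude."""
    stim = generate_stimulus("passive_sinusoid_pitch", 60.0, params)
    truth = AfferentGroundTruth(
        organ="canal", regularity="regular", resting_rate=90.0,
        response_lead_s=0.0, isi_shape=100.0, sv=0.5, sa=0.0,
    )
    rate = truth.rate(stim)
    assert np.ptp(rate) == pytest.approx(2 * 0.5 * 40.0, rel=1e-3)
    rec = simulate_afferent(truth, stim, seed=3)
    est = estimate_firing_rate(rec.spike_times, stim.t)
    from vestenc.spike_processing import cycle_modulation

    cs = cycle_modulation(est, fundamental_frequency=1.0)
    # cycle-averaged peak-to-peak: spiking noise adds an extreme-value
    # inflation on top of the true 40 sp/s depth
    assert 38.0 < cs.modulation < 75.0
    assert cs.mean_rate == pytest.approx(90.0, rel=0.03)


def test_rate_count_consistency(passive_low_120s):
    truth = AfferentGroundTruth(
        organ="otolith", regularity="irregular", resting_rate=70.0,
        response_lead_s=0.0, isi_shape=4.0, sa=200.0, sj=0.0,
    )
    rec = simulate_afferent(truth, passive_low_120s, seed=5)
    expected = np.sum(truth.rate(passive_low_120s)) / FS
    n = rec.spike_times.size
    assert n == pytest.approx(expected, rel=4.0 / np.sqrt(expected / 4.0))


@pytest.mark.parametrize("kappa,cv", [(4.0, 0.5), (25.0, 0.2), (100.0, 0.1)])
def test_renewal_regularity_tracks_gamma_shape(kappa, cv):
    """Resting interspike CV approximates 1/sqrt(kappa)."""
    n = int(120 * FS)
    still = StimulusTrace(
        t=np.arange(n) / FS, pitch_velocity=np.zeros(n),
        linear_acceleration=np.zeros(n), condition="passive_low", sample_rate=FS,
    )
    truth = AfferentGroundTruth(
        organ="canal", regularity="regular" if cv < 0.15 else "irregular",
        resting_rate=70.0, response_lead_s=0.0, isi_shape=kappa, sv=0.0, sa=0.0,
    )
    rec = simulate_afferent(truth, still, seed=int(kappa))
    isis = np.diff(rec.spike_times)
    assert isis.std() / isis.mean() == pytest.approx(cv, rel=0.1)


def test_sigmoid_afferent_cutoff_under_running(running_120s):
    """High-gain saturating afferent: zero-rate dwell and mean above rest."""
    sig = SigmoidParams.with_unit_gain_resting(60.0, 180.0)
    truth = AfferentGroundTruth(
        organ="otolith", regularity="irregular", resting_rate=60.0,
        response_lead_s=0.01, isi_shape=4.0, sa=450.0, sj=0.0, nonlinearity=sig,
    )
    rate = truth.rate(running_120s)
    assert np.mean(rate < 0.5) > 0.005
    assert rate.mean() > 60.0
    assert rate.min() >= 0.0 and rate.max() <= sig.c3


def test_simulation_determinism(passive_low_120s, linear_canal_truth):
    r1 = simulate_afferent(linear_canal_truth, passive_low_120s, seed=42)
    r2 = simulate_afferent(linear_canal_truth, passive_low_120s, seed=42)
    assert np.array_equal(r1.spike_times, r2.spike_times)


# -------------------------------------------------------------------- cohort


def test_default_cohort_class_counts():
    cfg = CohortConfig(duration_s=8.0, resting_duration_s=10.0)
    cohort = generate_cohort(cfg, seed=1)
    by_class = {}
    for aff_id, truth in cohort.truths.items():
        by_class.setdefault((truth.organ, truth.regularity), set()).add(aff_id)
    assert len(by_class[("canal", "regular")]) == 15
    assert len(by_class[("canal", "irregular")]) == 17
    assert len(by_class[("otolith", "regular")]) == 9
    assert len(by_class[("otolith", "irregular")]) == 14
    # within-afferent design: every afferent recorded in every condition
    for aff_id in cohort.truths:
        conds = {r.condition for r in cohort.for_afferent(aff_id)}
        assert conds == set(CONDITIONS)


def test_cohort_determinism():
    counts = {("otolith", "irregular"): 2}
    cfg = CohortConfig(counts=counts, duration_s=10.0, resting_duration_s=10.0)
    c1 = generate_cohort(cfg, seed=9)
    c2 = generate_cohort(cfg, seed=9)
    for r1, r2 in zip(c1.recordings, c2.recordings):
        assert np.array_equal(r1.spike_times, r2.spike_times)
    assert c1.truths.keys() == c2.truths.keys()
    for k in c1.truths:
        assert c1.truths[k] == c2.truths[k]


def test_cohort_regularity_classes_verified():
    counts = {("canal", "regular"): 2, ("canal", "irregular"): 2}
    cfg = CohortConfig(counts=counts, duration_s=5.0, resting_duration_s=20.0)
    cohort = generate_cohort(cfg, seed=11)
    from vestenc.spike_processing import interspike_regularity

    for aff_id, truth in cohort.truths.items():
        m = interspike_regularity(cohort.resting_spikes[aff_id], min_isis=100)
        assert m.class_label == truth.regularity


def test_empty_cohort_rejected():
    with pytest.raises(ValueError):
        generate_cohort(CohortConfig(counts={}), seed=0)
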