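"""Synthetic head-motion stimuli and vestibular afferent simulator.

This module provides the ground-truth test bed for the whole analysis chain:
condition-specific head-motion stimuli whose amplitude statistics are
calibrated analytically before any sampling, and spiking afferents of the
four classes (regular/irregular x canal/otolith) built as a linear filter,
an optional static nonlinearity, and inhomogeneous gamma-renewal spiking.

Stimulus conditions
-------------------
``passive_sinusoid_translation`` / ``passive_sinusoid_pitch``
    Exact sinusoids (1 Hz, ±0.2 g translation; 40 deg/s pitch velocity with a
    ±0.2 g gravito-inertial component in quadrature), the classical afferent
    characterization protocol.
``passive_low`` / ``walking``
    A matched pair: quasi-periodic motion, x(t) = A sin(θ(t)) + s g(t), where
    θ drifts slowly around the step rate and g is band-limited Gaussian
    noise.  Both members share the configured SD and spectral shape; the
    periodic/noise split is calibrated separately so that the fraction of
    samples beyond ±1.5 SD of the passive reference reproduces the target
    statistics (acceleration: 3 % passive, 5 % walking; rotation: 3 %, 2 %).
``passive_high`` / ``running``
    A matched pair with higher SD and power.  The net-acceleration channel is
    a two-component Gaussian scale mixture (a "body" process with occasional
    high-scale bursts) calibrated in closed form so that 15 % of samples fall
    beyond ±1.5 SD of the walking-matched passive reference; the rotational
    channel stays quasi-periodic at a faster step rate (4 % tail target).

The quasi-periodic marginal is an arcsine ⊕ Gaussian convolution and the
mixture marginal is exact by construction, so both tail calibrations are
computed deterministically (quadrature + root finding) before sampling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.optimize import brentq
from scipy.stats import norm

from ._signal import (
    DERIV_SMOOTH_HZ,
    advance,
    band_limited_noise,
    check_uniform_grid,
    smoothed_derivative,
)
from .ln_cascade import SigmoidParams

__all__ = [
    "CONDITIONS",
    "StimulusParams",
    "StimulusTrace",
    "AfferentGroundTruth",
    "SimulatedRecording",
    "Cohort",
    "CohortConfig",
    "ClassParams",
    "generate_stimulus",
    "simulate_afferent",
    "generate_cohort",
    "quasiperiodic_tail",
    "calibrate_quasiperiodic",
    "scale_mixture_tail",
    "calibrate_scale_mixture",
    "DEFAULT_CLASS_COUNTS",
]

CONDITIONS = (
    "passive_sinusoid_translation",
    "passive_sinusoid_pitch",
    "passive_low",
    "passive_high",
    "walking",
    "running",
)
_STOCHASTIC = {"passive_low", "passive_high", "walking", "running"}


# --------------------------------------------------------------------------
# generator configuration
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class StimulusParams:
    """Generator defaults defining the study conditions.

    Tail targets are the fractions of samples beyond ±1.5 SD of the
    walking-matched passive reference; SD ratios scale the locomotion
    conditions relative to that reference.
    """

    sample_rate: float = 1000.0
    # passive sinusoidal characterization
    sinusoid_freq_hz: float = 1.0
    sinusoid_accel_amp_g: float = 0.2
    sinusoid_vel_amp_dps: float = 40.0
    # walking-matched reference scales
    accel_sd_g: float = 0.08
    vel_sd_dps: float = 15.0
    # spectral structure
    step_rate_walk_hz: float = 2.0
    step_rate_run_hz: float = 3.2
    noise_cutoff_walk_hz: float = 4.0
    noise_cutoff_run_hz: float = 8.0
    freq_jitter: float = 0.05
    # amplitude-statistics calibration targets (fractions beyond ±1.5 SD_ref)
    accel_tail_passive: float = 0.03
    accel_tail_walking: float = 0.05
    accel_tail_running: float = 0.15
    vel_tail_passive: float = 0.03
    vel_tail_walking: float = 0.02
    vel_tail_running: float = 0.04
    # locomotion SD ratios relative to the walking-matched reference
    run_accel_sd_ratio: float = 1.8
    run_vel_sd_ratio: float = 1.05
    # running scale mixture: weight of the low-scale "body" component and
    # switching bandwidth of the burst process
    mixture_weight: float = 0.88
    mixture_switch_hz: float = 1.5
    # static head orientation (pitch of gravity in the head frame, deg)
    head_pitch_deg: float = 15.0
    tail_threshold: float = 1.5


# --------------------------------------------------------------------------
# analytic tail calibration
# --------------------------------------------------------------------------

_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(400)


def quasiperiodic_tail(r: float, threshold_sd: float) -> float:
    """P(|X| > threshold_sd * SD) for X = A sin(U) + s Z, U uniform, Z normal.

    ``r`` in [0, 1) is the periodic share of the amplitude: A = sqrt(2) r SD,
    s = sqrt(1 - r^2) SD.  Computed by Gauss–Legendre quadrature over the
    phase; exact up to quadrature error, no sampling involved.
    """
    if not 0 <= r < 1:
        raise ValueError("periodic share r must be in [0, 1)")
    a = math.sqrt(2.0) * r
    s = math.sqrt(1.0 - r * r)
    u = 0.5 * np.pi * (_GL_NODES + 1.0)  # phase in (0, pi)
    w = 0.5 * np.pi * _GL_WEIGHTS
    vals = norm.sf((threshold_sd - a * np.sin(u)) / s) + norm.sf(
        (threshold_sd + a * np.sin(u)) / s
    )
    return float(np.sum(w * vals) / np.pi)


@lru_cache(maxsize=64)
def calibrate_quasiperiodic(target_tail: float, threshold_sd: float = 1.5) -> float:
    """Periodic share r giving the requested tail fraction at the threshold.

    The family spans (0, 2*Phi(-threshold)] — from arbitrarily light tails in
    the sinusoid-dominated limit up to the Gaussian tail.  Raises if the
    target is outside that range (e.g. a heavy-tail target, which needs the
    scale-mixture family instead).
    """
    gauss_tail = 2.0 * norm.sf(threshold_sd)
    if not 0 < target_tail < gauss_tail:
        raise ValueError(
            f"tail target {target_tail} unachievable for the quasi-periodic "
            f"family at threshold {threshold_sd} (range (0, {gauss_tail:.4f}))"
        )
    if threshold_sd <= math.sqrt(2.0):
        raise ValueError(
            "threshold must exceed sqrt(2) SD for light-tail calibration"
        )
    return float(
        brentq(
            lambda r: quasiperiodic_tail(r, threshold_sd) - target_tail,
            1e-9,
            1.0 - 1e-9,
            xtol=1e-12,
        )
    )


def scale_mixture_tail(
    s1: float, s2: float, weight: float, threshold: float
) -> float:
    """P(|X| > threshold) for X ~ w N(0, s1²) + (1-w) N(0, s2²)."""
    return float(
        2.0 * (weight * norm.sf(threshold / s1) + (1 - weight) * norm.sf(threshold / s2))
    )


@lru_cache(maxsize=64)
def calibrate_scale_mixture(
    target_tail: float,
    sd_ratio: float,
    weight: float = 0.88,
    threshold_sd: float = 1.5,
) -> tuple[float, float]:
    """Component scales (s1, s2) in units of the reference SD.

    The mixture has total SD ``sd_ratio`` (relative to the reference) and its
    tail beyond ``threshold_sd`` reference SDs equals ``target_tail``.  The
    closed-form tail expression is solved for the body scale s1, with s2
    fixed by the variance constraint.
    """
    var = sd_ratio**2

    def tail_of(s1: float) -> float:
        s2 = math.sqrt((var - weight * s1**2) / (1 - weight))
        return scale_mixture_tail(s1, s2, weight, threshold_sd)

    lo = 1e-3 * sd_ratio
    hi = (1.0 - 1e-9) * sd_ratio / math.sqrt(weight)
    t_lo, t_hi = tail_of(lo), tail_of(hi)
    if not min(t_lo, t_hi) <= target_tail <= max(t_lo, t_hi):
        raise ValueError(
            f"tail target {target_tail} unachievable for scale mixture with "
            f"sd_ratio={sd_ratio}, weight={weight} "
            f"(achievable range [{t_lo:.4f}, {t_hi:.4f}])"
        )
    s1 = float(brentq(lambda s: tail_of(s) - target_tail, lo, hi, xtol=1e-12))
    s2 = math.sqrt((var - weight * s1**2) / (1 - weight))
    return s1, s2


# --------------------------------------------------------------------------
# stimulus traces
# --------------------------------------------------------------------------


@dataclass
class StimulusTrace:
    """Uniformly sampled head-motion channels for one condition.

    ``pitch_velocity`` is in deg/s, ``linear_acceleration`` is the net
    gravito-inertial acceleration (g) along the afferent's preferred axis.
    ``pitch_acceleration`` (deg/s²) and ``jerk`` (g/s) are derived lazily by
    the shared smoothing + central-difference convention.  ``accel_forward``
    and ``accel_vertical`` carry the gravity-including axes used for head
    orientation estimates.
    """

    t: np.ndarray
    pitch_velocity: np.ndarray
    linear_acceleration: np.ndarray
    condition: str
    sample_rate: float
    accel_forward: np.ndarray | None = None
    accel_vertical: np.ndarray | None = None
    deriv_smooth_hz: float = DERIV_SMOOTH_HZ
    _pitch_acceleration: np.ndarray | None = field(
        default=None, repr=False, compare=False
    )
    _jerk: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        step = check_uniform_grid(self.t)
        if not math.isclose(step, 1.0 / self.sample_rate, rel_tol=1e-6):
            raise ValueError("time grid does not match the stated sample rate")
        n = len(self.t)
        for name in ("pitch_velocity", "linear_acceleration"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n,):
                raise ValueError(f"{name} must match the time grid")
            setattr(self, name, arr)

    @property
    def pitch_acceleration(self) -> np.ndarray:
        """Angular acceleration (deg/s²), derivative of pitch velocity."""
        if self._pitch_acceleration is None:
            self._pitch_acceleration = smoothed_derivative(
                self.pitch_velocity, self.sample_rate, self.deriv_smooth_hz
            )
        return self._pitch_acceleration

    @property
    def jerk(self) -> np.ndarray:
        """Linear jerk (g/s), derivative of net linear acceleration."""
        if self._jerk is None:
            self._jerk = smoothed_derivative(
                self.linear_acceleration, self.sample_rate, self.deriv_smooth_hz
            )
        return self._jerk

    @property
    def duration(self) -> float:
        return len(self.t) / self.sample_rate

    def channel(self, name: str) -> np.ndarray:
        return {
            "pitch_velocity": self.pitch_velocity,
            "pitch_acceleration": self.pitch_acceleration,
            "linear_acceleration": self.linear_acceleration,
            "jerk": self.jerk,
        }[name]


def _quasiperiodic_channel(
    rng: np.random.Generator,
    n: int,
    fs: float,
    sd: float,
    r: float,
    f0: float,
    noise_cutoff: float,
    freq_jitter: float,
) -> np.ndarray:
    """Sample the quasi-periodic process A sin(theta(t)) + s g(t).

    The instantaneous step rate drifts slowly (band-limited frequency noise,
    relative SD ``freq_jitter``), so the phase is smooth and the process and
    its derivatives keep their power near the fundamental.  The initial
    phase is uniform, so the periodic component's marginal is exactly the
    arcsine distribution whatever the drift realization.
    """
    amp = math.sqrt(2.0) * r * sd
    s = math.sqrt(1.0 - r * r) * sd
    theta0 = rng.uniform(0.0, 2.0 * np.pi)
    freq_dev = f0 * freq_jitter * band_limited_noise(rng, n, fs, 0.5)
    theta = theta0 + 2.0 * np.pi * np.cumsum(f0 + freq_dev) / fs
    x = amp * np.sin(theta)
    if s > 0:
        x = x + s * band_limited_noise(rng, n, fs, noise_cutoff)
    return x


def _scale_mixture_channel(
    rng: np.random.Generator,
    n: int,
    fs: float,
    ref_sd: float,
    s1: float,
    s2: float,
    weight: float,
    noise_cutoff: float,
    switch_hz: float,
) -> np.ndarray:
    """Sample the burst scale mixture with slow component switching.

    The component label follows a thresholded slow Gaussian process that is
    independent of both band-limited carriers, so the stationary marginal is
    exactly the calibrated two-component mixture.
    """
    g1 = band_limited_noise(rng, n, fs, noise_cutoff)
    g2 = band_limited_noise(rng, n, fs, noise_cutoff)
    u = band_limited_noise(rng, n, fs, switch_hz)
    burst = u > norm.ppf(weight)
    return ref_sd * np.where(burst, s2 * g2, s1 * g1)


def generate_stimulus(
    condition: str,
    duration: float,
    params: StimulusParams | None = None,
    seed: int | None = None,
) -> StimulusTrace:
    """Generate one condition's head-motion trace.

    ``seed`` is required for the stochastic (naturalistic) conditions.  A
    zero amplitude/SD parameter yields all-zero motion channels.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    if duration <= 0:
        raise ValueError("duration must be positive")
    p = params or StimulusParams()
    fs = p.sample_rate
    n = int(round(duration * fs))
    t = np.arange(n) / fs

    if condition in _STOCHASTIC:
        if seed is None:
            raise ValueError(f"seed required for stochastic condition {condition!r}")
        rng = np.random.default_rng(seed)

    thr = p.tail_threshold
    if condition == "passive_sinusoid_translation":
        vel = np.zeros(n)
        acc = p.sinusoid_accel_amp_g * np.sin(2 * np.pi * p.sinusoid_freq_hz * t)
    elif condition == "passive_sinusoid_pitch":
        w = 2 * np.pi * p.sinusoid_freq_hz
        vel = p.sinusoid_vel_amp_dps * np.sin(w * t)
        # gravito-inertial component follows head position: 90 deg behind velocity
        acc = p.sinusoid_accel_amp_g * np.sin(w * t - np.pi / 2)
    elif condition in ("passive_low", "walking"):
        acc_target = (
            p.accel_tail_passive if condition == "passive_low" else p.accel_tail_walking
        )
        vel_target = (
            p.vel_tail_passive if condition == "passive_low" else p.vel_tail_walking
        )
        acc = _stochastic_qp(
            rng, n, fs, p.accel_sd_g, acc_target, thr, p.step_rate_walk_hz,
            p.noise_cutoff_walk_hz, p.freq_jitter,
        )
        vel = _stochastic_qp(
            rng, n, fs, p.vel_sd_dps, vel_target, thr, p.step_rate_walk_hz,
            p.noise_cutoff_walk_hz, p.freq_jitter,
        )
    elif condition in ("running", "passive_high"):
        acc_sd = p.accel_sd_g * p.run_accel_sd_ratio
        if acc_sd == 0:
            acc = np.zeros(n)
        else:
            s1, s2 = calibrate_scale_mixture(
                p.accel_tail_running, p.run_accel_sd_ratio, p.mixture_weight, thr
            )
            acc = _scale_mixture_channel(
                rng, n, fs, p.accel_sd_g, s1, s2, p.mixture_weight,
                p.noise_cutoff_run_hz, p.mixture_switch_hz,
            )
        vel = _stochastic_qp(
            rng, n, fs, p.vel_sd_dps * p.run_vel_sd_ratio, p.vel_tail_running,
            thr / p.run_vel_sd_ratio, p.step_rate_run_hz,
            p.noise_cutoff_run_hz, p.freq_jitter,
        )

    tilt = math.radians(p.head_pitch_deg)
    trace = StimulusTrace(
        t=t,
        pitch_velocity=vel,
        linear_acceleration=acc,
        condition=condition,
        sample_rate=fs,
        accel_forward=math.sin(tilt) + acc * math.cos(tilt),
        accel_vertical=math.cos(tilt) * np.ones(n) - acc * math.sin(tilt),
    )
    return trace


def _stochastic_qp(rng, n, fs, sd, target, threshold_sd, f0, cutoff, jitter):
    if sd == 0:
        return np.zeros(n)
    r = calibrate_quasiperiodic(target, threshold_sd)
    return _quasiperiodic_channel(rng, n, fs, sd, r, f0, cutoff, jitter)


# --------------------------------------------------------------------------
# afferent ground truth and spiking
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class AfferentGroundTruth:
    """True parameters of one simulated afferent.

    Canal afferents carry (sv, sa): sensitivity to pitch velocity
    ((sp/s)/(deg/s)) and angular acceleration ((sp/s)/(deg/s²)).  Otolith
    afferents carry (sa, sj): sensitivity to net linear acceleration
    ((sp/s)/g) and jerk ((sp/s)/(g/s)).  ``resting_rate`` doubles as the
    linear bias, so the afferent fires at its resting discharge for zero
    motion.  ``isi_shape`` is the gamma-renewal shape κ: resting interspike
    CV ≈ 1/sqrt(κ).
    """

    organ: str
    regularity: str
    resting_rate: float
    response_lead_s: float
    isi_shape: float
    sv: float | None = None
    sa: float | None = None
    sj: float | None = None
    nonlinearity: SigmoidParams | str = "linear-rectified"

    def __post_init__(self) -> None:
        if self.organ not in ("canal", "otolith"):
            raise ValueError("organ must be 'canal' or 'otolith'")
        if self.regularity not in ("regular", "irregular"):
            raise ValueError("regularity must be 'regular' or 'irregular'")
        if self.resting_rate <= 0:
            raise ValueError("resting rate must be positive")
        if self.isi_shape < 1:
            raise ValueError("gamma shape must be >= 1")
        if self.organ == "canal":
            if self.sv is None or self.sa is None or self.sj is not None:
                raise ValueError("canal afferents use (sv, sa) and no sj")
        else:
            if self.sa is None or self.sj is None or self.sv is not None:
                raise ValueError("otolith afferents use (sa, sj) and no sv")
        if not (
            self.nonlinearity == "linear-rectified"
            or isinstance(self.nonlinearity, SigmoidParams)
        ):
            raise ValueError("nonlinearity must be 'linear-rectified' or SigmoidParams")

    def drive(self, stim: StimulusTrace) -> np.ndarray:
        """Linear stage output: coefficients applied to the lead-advanced stimulus."""
        m = int(round(self.response_lead_s * stim.sample_rate))
        if self.organ == "canal":
            x = self.sv * advance(stim.pitch_velocity, m) + self.sa * advance(
                stim.pitch_acceleration, m
            )
        else:
            x = self.sa * advance(stim.linear_acceleration, m) + self.sj * advance(
                stim.jerk, m
            )
        return self.resting_rate + x

    def rate(self, stim: StimulusTrace) -> np.ndarray:
        """Instantaneous firing rate: linear stage through the nonlinearity."""
        z = self.drive(stim)
        if self.nonlinearity == "linear-rectified":
            return np.maximum(z, 0.0)
        return self.nonlinearity(z)


@dataclass
class SimulatedRecording:
    """Spike train of one afferent under one stimulus, with ground truth."""

    stimulus: StimulusTrace
    spike_times: np.ndarray
    truth: AfferentGroundTruth
    seed: int
    afferent_id: str = ""

    def __post_init__(self) -> None:
        st = np.asarray(self.spike_times, dtype=float)
        if st.size and (np.any(np.diff(st) <= 0)):
            raise ValueError("spike times must be strictly increasing")
        if st.size and (st[0] < self.stimulus.t[0] or st[-1] > self.stimulus.duration):
            raise ValueError("spike times outside the stimulus span")
        self.spike_times = st

    @property
    def condition(self) -> str:
        return self.stimulus.condition


def _gamma_renewal_spikes(
    rng: np.random.Generator, rate: np.ndarray, fs: float, kappa: float
) -> np.ndarray:
    """Inhomogeneous gamma-renewal spike times by time rescaling.

    In operational time Λ(t) = ∫ rate dt the train is an ordinary renewal
    process with Gamma(κ, 1/κ) intervals (unit mean), so the expected count
    equals Λ(T) and the interval CV is 1/sqrt(κ); spikes are mapped back by
    inverting Λ.
    """
    n = rate.size
    edges = np.arange(n + 1) / fs
    lam = np.concatenate([[0.0], np.cumsum(rate) / fs])
    total = lam[-1]
    if total <= 0:
        return np.array([])
    draws = []
    acc = 0.0
    while acc < total:
        want = max(int((total - acc) + 10.0 * math.sqrt((total - acc) / kappa)), 64)
        batch = rng.gamma(kappa, 1.0 / kappa, size=want)
        draws.append(batch)
        acc += float(batch.sum())
    cum = np.cumsum(np.concatenate(draws))
    cum = cum[cum < total]
    times = np.interp(cum, lam, edges)
    # numerical safety: drop any zero-length interval created by flat Λ spans
    if times.size > 1:
        keep = np.concatenate([[True], np.diff(times) > 0])
        times = times[keep]
    return times


def simulate_afferent(
    truth: AfferentGroundTruth,
    stim: StimulusTrace,
    seed: int,
    afferent_id: str = "",
) -> SimulatedRecording:
    """Simulate one afferent's spike train in response to a stimulus."""
    rng = np.random.default_rng(seed)
    rate = truth.rate(stim)
    spikes = _gamma_renewal_spikes(rng, rate, stim.sample_rate, truth.isi_shape)
    return SimulatedRecording(
        stimulus=stim, spike_times=spikes, truth=truth, seed=seed,
        afferent_id=afferent_id,
    )


# --------------------------------------------------------------------------
# cohorts
# --------------------------------------------------------------------------

DEFAULT_CLASS_COUNTS = {
    ("canal", "regular"): 15,
    ("canal", "irregular"): 17,
    ("otolith", "regular"): 9,
    ("otolith", "irregular"): 14,
}


@dataclass(frozen=True)
class ClassParams:
    """Ground-truth parameter ranges for one afferent class.

    ``gain1`` is the primary sensitivity (sv for canal in (sp/s)/(deg/s),
    sa for otolith in (sp/s)/g); ``gain2`` the derivative sensitivity
    (sa for canal, sj for otolith).  ``sigmoid_c3_ratio`` sets the sigmoid
    ceiling as a multiple of the resting rate (ceiling > 2x resting puts the
    operating point below the inflection, so cutoff precedes saturation);
    ``sigmoid_width_factor`` sets sqrt(c1) as a multiple of the afferent's
    drive SD under the running stimulus, keeping the quasi-linear core wide
    while burst excursions reach cutoff.
    """

    r0_range: tuple[float, float]
    gain1_range: tuple[float, float]
    gain2_range: tuple[float, float]
    lead_range_s: tuple[float, float]
    isi_shape: float
    nonlinearity: str = "linear-rectified"  # or "sigmoid"
    sigmoid_c3_ratio: tuple[float, float] = (3.0, 5.0)


DEFAULT_CLASS_PARAMS = {
    # Linear classes carry their response dynamics in the derivative
    # coefficient (acceleration for canal, jerk for otolith) with zero pure
    # lead: lead and coefficient rotation are interchangeable under
    # narrowband stimulation, so the derivative term IS the phase lead.
    ("canal", "regular"): ClassParams(
        r0_range=(70.0, 100.0), gain1_range=(0.3, 0.5), gain2_range=(0.015, 0.025),
        lead_range_s=(0.0, 0.0), isi_shape=100.0,
    ),
    ("canal", "irregular"): ClassParams(
        r0_range=(50.0, 90.0), gain1_range=(0.8, 1.2), gain2_range=(0.04, 0.06),
        lead_range_s=(0.0, 0.0), isi_shape=4.0,
    ),
    ("otolith", "regular"): ClassParams(
        r0_range=(70.0, 100.0), gain1_range=(40.0, 80.0), gain2_range=(0.5, 1.5),
        lead_range_s=(0.0, 0.0), isi_shape=100.0,
    ),
    ("otolith", "irregular"): ClassParams(
        r0_range=(60.0, 90.0), gain1_range=(350.0, 450.0), gain2_range=(0.0, 0.0),
        lead_range_s=(0.008, 0.015), isi_shape=4.0, nonlinearity="sigmoid",
    ),
}


@dataclass
class CohortConfig:
    """Within-afferent study design: every afferent sees every condition."""

    counts: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_COUNTS))
    class_params: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_PARAMS))
    conditions: tuple = CONDITIONS
    duration_s: float = 120.0
    resting_duration_s: float = 30.0
    stimulus_params: StimulusParams = field(default_factory=StimulusParams)


@dataclass
class Cohort:
    """Simulated recordings for all afferents under all conditions."""

    recordings: list
    resting_spikes: dict
    truths: dict
    stimuli: dict
    config: CohortConfig
    seed: int

    def for_afferent(self, afferent_id: str) -> list:
        return [r for r in self.recordings if r.afferent_id == afferent_id]


def _draw_truth(
    rng: np.random.Generator, organ: str, regularity: str, cp: ClassParams,
    stim_params: StimulusParams,
) -> AfferentGroundTruth:
    def u(lohi):
        lo, hi = lohi
        if lo > hi:
            raise ValueError(f"invalid range {lohi}")
        return float(rng.uniform(lo, hi)) if hi > lo else float(lo)

    r0 = u(cp.r0_range)
    g1, g2 = u(cp.gain1_range), u(cp.gain2_range)
    lead = u(cp.lead_range_s)
    if cp.nonlinearity == "sigmoid":
        nl: SigmoidParams | str = SigmoidParams.with_unit_gain_resting(
            r0, u(cp.sigmoid_c3_ratio) * r0
        )
    else:
        nl = "linear-rectified"
    kw = dict(sv=g1, sa=g2) if organ == "canal" else dict(sa=g1, sj=g2)
    return AfferentGroundTruth(
        organ=organ, regularity=regularity, resting_rate=r0,
        response_lead_s=lead, isi_shape=cp.isi_shape, nonlinearity=nl, **kw,
    )


def generate_cohort(config: CohortConfig | None = None, seed: int = 0) -> Cohort:
    """Simulate the full within-afferent cohort.

    One stimulus trace is generated per condition (shared session), then each
    afferent is simulated against every condition with its own spiking seed,
    plus a stimulus-free resting recording used for regularity
    classification.  Identical config + seed reproduces the cohort
    bit-for-bit.
    """
    config = config or CohortConfig()
    if not config.counts or all(v == 0 for v in config.counts.values()):
        raise ValueError("cohort needs at least one afferent class with count > 0")
    rng = np.random.default_rng(seed)
    p = config.stimulus_params

    stimuli = {
        cond: generate_stimulus(
            cond, config.duration_s, p, seed=int(rng.integers(2**31 - 1))
        )
        for cond in config.conditions
    }
    resting_stim = StimulusTrace(
        t=np.arange(int(round(config.resting_duration_s * p.sample_rate)))
        / p.sample_rate,
        pitch_velocity=np.zeros(
            int(round(config.resting_duration_s * p.sample_rate))
        ),
        linear_acceleration=np.zeros(
            int(round(config.resting_duration_s * p.sample_rate))
        ),
        condition="passive_low",
        sample_rate=p.sample_rate,
    )

    recordings: list[SimulatedRecording] = []
    resting: dict[str, np.ndarray] = {}
    truths: dict[str, AfferentGroundTruth] = {}
    for (organ, regularity), count in sorted(config.counts.items()):
        if count < 0:
            raise ValueError("class counts must be non-negative")
        cp = config.class_params[(organ, regularity)]
        for i in range(count):
            aff_id = f"{organ[:3]}_{regularity[:3]}_{i:02d}"
            truth = _draw_truth(rng, organ, regularity, cp, p)
            truths[aff_id] = truth
            rest = simulate_afferent(
                truth, resting_stim, seed=int(rng.integers(2**31 - 1)),
                afferent_id=aff_id,
            )
            resting[aff_id] = rest.spike_times
            _verify_regularity(truth, rest.spike_times)
            for cond in config.conditions:
                recordings.append(
                    simulate_afferent(
                        truth, stimuli[cond],
                        seed=int(rng.integers(2**31 - 1)), afferent_id=aff_id,
                    )
                )
    return Cohort(
        recordings=recordings, resting_spikes=resting, truths=truths,
        stimuli=stimuli, config=config, seed=seed,
    )


def _verify_regularity(truth: AfferentGroundTruth, resting_spikes: np.ndarray) -> None:
    """Check the simulated resting discharge lands in the intended CV* class."""
    from .spike_processing import interspike_regularity

    if resting_spikes.size < 3:
        raise ValueError("resting recording produced too few spikes to classify")
    metrics = interspike_regularity(resting_spikes, min_isis=2)
    if metrics.class_label != truth.regularity:
        raise ValueError(
            f"afferent drawn as {truth.regularity} classified as "
            f"{metrics.class_label} (CV* = {metrics.cv_star:.3f}); "
            "adjust isi_shape for this class"
        )
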