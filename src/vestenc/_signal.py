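"""Shared signal-processing helpers: filtering, derivatives, alignment.

All head-motion channels in this package live on a uniform time grid.  The
smoothing/derivative convention used everywhere (stimulus generation, model
fitting) is: zero-phase low-pass at ``DERIV_SMOOTH_HZ`` followed by central
differences, so that a derived channel and its parent stay consistent.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

#: Zero-phase smoothing cutoff (Hz) applied before numerical differentiation.
DERIV_SMOOTH_HZ = 125.0


def lowpass(x: np.ndarray, fs: float, cutoff_hz: float, order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth low-pass filter."""
    if cutoff_hz >= fs / 2:
        return np.asarray(x, dtype=float)
    sos = signal.butter(order, cutoff_hz, fs=fs, output="sos")
    return signal.sosfiltfilt(sos, np.asarray(x, dtype=float))


def smoothed_derivative(
    x: np.ndarray, fs: float, smooth_hz: float = DERIV_SMOOTH_HZ
) -> np.ndarray:
    """Central-difference derivative after the shared low-pass smoothing step."""
    xs = lowpass(x, fs, smooth_hz)
    return np.gradient(xs, 1.0 / fs)


def band_limited_noise(
    rng: np.random.Generator, n: int, fs: float, cutoff_hz: float, order: int = 4
) -> np.ndarray:
    """Unit-variance Gaussian noise low-passed at ``cutoff_hz``.

    The normalization uses the filter's analytic noise gain (sum of squared
    impulse-response samples) rather than the realized sample variance, so the
    *expected* variance is exactly 1 and the marginal distribution is exactly
    standard normal.
    """
    sos = signal.butter(order, cutoff_hz, fs=fs, output="sos")
    # impulse response long enough for the slowest pole to decay
    m = max(64, int(16 * fs / cutoff_hz))
    h = signal.sosfilt(sos, np.r_[1.0, np.zeros(m - 1)])
    gain = float(np.sqrt(np.sum(h**2)))
    white = rng.standard_normal(n + m)
    return signal.sosfilt(sos, white)[m:] / gain


def advance(x: np.ndarray, lag_samples: int) -> np.ndarray:
    """Shift a signal *forward* in time by ``lag_samples`` (edge-hold padding).

    ``advance(x, m)[i] == x[i + m]`` for in-range indices: a positive shift
    yields the signal's future values, which is how a neuron's response lead
    is applied to the head-motion channels.
    """
    x = np.asarray(x)
    if lag_samples == 0:
        return x.copy()
    out = np.empty_like(x)
    if lag_samples > 0:
        out[:-lag_samples] = x[lag_samples:]
        out[-lag_samples:] = x[-1]
    else:
        out[-lag_samples:] = x[:lag_samples]
        out[: -lag_samples] = x[0]
    return out


def check_uniform_grid(t: np.ndarray, rtol: float = 1e-6) -> float:
    """Validate a strictly increasing uniform time grid; return its step."""
    t = np.asarray(t, dtype=float)
    if t.ndim != 1 or t.size < 2:
        raise ValueError("time grid needs at least two samples")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError("time grid must be strictly increasing")
    step = float(np.median(dt))
    if np.any(np.abs(dt - step) > rtol * step + 1e-12):
        raise ValueError("time grid must be uniform")
    return step
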