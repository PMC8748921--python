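"""Head-motion statistics used to compare stimulation conditions.

Spectral power (averaged modified periodograms), normalized cumulative
spectra and their area, amplitude-distribution tails relative to a passive
reference band (±k SD), SD/kurtosis summaries, and the mean head orientation
relative to gravity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal, stats

from ._signal import lowpass

__all__ = [
    "SpectralSummary",
    "AmplitudeStats",
    "spectral_power",
    "tail_fraction",
    "distribution_summary",
    "mean_orientation",
]


@dataclass
class SpectralSummary:
    """PSD with its normalized cumulative curve and band-limited area."""

    frequencies: np.ndarray
    psd: np.ndarray
    cumulative_normalized: np.ndarray
    auc_cumulative: float


@dataclass
class AmplitudeStats:
    """Amplitude-distribution summary of one motion channel.

    ``kurtosis`` uses the non-excess (Pearson) convention: a Gaussian
    channel scores 3.
    """

    sd: float
    kurtosis: float
    tail_fraction: float = float("nan")
    reference_sd: float = float("nan")
    mean_orientation: float = float("nan")


def spectral_power(
    x: np.ndarray,
    fs: float,
    window_s: float = 2.0,
    band: tuple[float, float] = (0.0, 15.0),
) -> SpectralSummary:
    """Averaged-periodogram PSD (Welch, 50 % overlap) with cumulative summary.

    The PSD integrates to the channel variance (Parseval); the cumulative
    curve is normalized to end at 1 and its area is taken over ``band`` (a
    spectrum concentrated at low frequencies has a larger area than one
    shifted toward high frequencies).
    """
    x = np.asarray(x, dtype=float)
    nperseg = int(round(window_s * fs))
    if x.size < nperseg:
        raise ValueError("record shorter than one spectral window")
    freqs, psd = signal.welch(x, fs=fs, nperseg=nperseg, detrend="constant")
    cum = np.concatenate([[0.0], np.cumsum(0.5 * (psd[1:] + psd[:-1]) * np.diff(freqs))])
    total = cum[-1]
    if total <= 0:
        cumn = np.zeros_like(cum)
        auc = 0.0
    else:
        cumn = cum / total
        sel = (freqs >= band[0]) & (freqs <= band[1])
        auc = float(np.trapezoid(cumn[sel], freqs[sel]))
    return SpectralSummary(
        frequencies=freqs, psd=psd, cumulative_normalized=cumn, auc_cumulative=auc
    )


def tail_fraction(
    test_channel: np.ndarray, reference_channel: np.ndarray, k: float = 1.5
) -> float:
    """Fraction of test samples beyond ±k SD of the reference distribution."""
    test = np.asarray(test_channel, dtype=float)
    ref = np.asarray(reference_channel, dtype=float)
    sd = ref.std()
    if sd == 0:
        raise ValueError("zero reference SD")
    return float(np.mean(np.abs(test - ref.mean()) > k * sd))


def distribution_summary(channel: np.ndarray) -> AmplitudeStats:
    """SD and non-excess kurtosis of a motion channel."""
    x = np.asarray(channel, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 samples")
    sd = float(x.std())
    if sd == 0:
        raise ValueError("kurtosis undefined for a constant channel")
    return AmplitudeStats(sd=sd, kurtosis=float(stats.kurtosis(x, fisher=False)))


def mean_orientation(
    forward_accel: np.ndarray,
    vertical_accel: np.ndarray,
    fs: float,
    lowpass_cutoff_hz: float = 0.5,
) -> float:
    """Mean pitch of the gravity vector in the head frame (deg).

    Both acceleration axes (g) are low-passed to isolate the
    gravity-dominated component; the pitch angle is the arctangent of the
    forward over the vertical component, averaged over the record.  Zero
    degrees puts gravity entirely on the vertical (dorsoventral) axis.
    """
    f = lowpass(np.asarray(forward_accel, float), fs, lowpass_cutoff_hz)
    v = lowpass(np.asarray(vertical_accel, float), fs, lowpass_cutoff_hz)
    mag = np.hypot(f, v)
    if np.any(mag < 1e-9):
        raise ValueError("zero gravity-component magnitude")
    return float(np.degrees(np.arctan2(f, v)).mean())
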