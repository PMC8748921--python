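"""Linear–nonlinear (LN) cascade model of vestibular afferent firing.

The cascade composes a single-channel linear stage,

    r(t) = St * H(t + lead) + r0,

with a static erf sigmoid,

    Tsig(x) = (c3 / 2) * (1 + erf((x - c2) / sqrt(2 * c1))),

so the predicted firing rate is N(t) = Tsig(St * H(t + lead) + r0).  H is the
head-motion channel the organ encodes: pitch angular velocity (deg/s) for
semicircular-canal afferents, net linear acceleration (g) for otolith
afferents.  The sigmoid captures the two firing-rate nonlinearities real
afferents show under vigorous stimulation — inhibitory cutoff at 0 sp/s and
saturation — while reducing to the linear model in its quasi-linear core.

Fitting proceeds in the stages used for real recordings:

1. ``estimate_response_lag`` — align rate and stimulus at the cross-
   correlation peak (positive lead = firing precedes motion);
2. ``determine_linear_range`` — keep samples with stimulus within mean ± 1 SD;
3. ``fit_linear_stage`` — least squares for (St, r0) on the masked samples;
4. ``bin_stimulus_response`` — average the firing rate in narrow stimulus
   bins (0.0004 g by default for otolith channels);
5. ``fit_sigmoid`` — nonlinear least squares of Tsig on the binned tuning
   expressed against the linear prediction.

The LN *bias* is the predicted rate at zero head motion, Tsig(r0), and the
LN *modulation* is the local slope there, St * Tsig'(r0) — the nonlinear
analogs of the linear model's intercept and gain, evaluated at the same
operating point so the two are directly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy.special import erf, erfinv

from ._signal import advance

__all__ = [
    "SigmoidParams",
    "BinnedTuning",
    "LNModel",
    "estimate_response_lag",
    "determine_linear_range",
    "fit_linear_stage",
    "bin_stimulus_response",
    "fit_sigmoid",
    "fit_ln_model",
    "DEFAULT_OTOLITH_BIN_G",
]

#: Stimulus bin width for otolith acceleration channels (g).
DEFAULT_OTOLITH_BIN_G = 0.0004


@dataclass(frozen=True)
class SigmoidParams:
    """Static-nonlinearity parameters.

    c1 : squared width of the transition (input units²), > 0
    c2 : inflection location (input units); Tsig(c2) = c3 / 2
    c3 : upper asymptote (sp/s), > 0
    """

    c1: float
    c2: float
    c3: float

    def __post_init__(self) -> None:
        if not (self.c1 > 0 and self.c3 > 0):
            raise ValueError("sigmoid requires c1 > 0 and c3 > 0")

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        return 0.5 * self.c3 * (1.0 + erf((x - self.c2) / np.sqrt(2.0 * self.c1)))

    def slope(self, x):
        """Derivative d Tsig / dx."""
        x = np.asarray(x, dtype=float)
        return (
            self.c3
            / np.sqrt(2.0 * np.pi * self.c1)
            * np.exp(-((x - self.c2) ** 2) / (2.0 * self.c1))
        )

    @classmethod
    def with_resting_point(cls, r0: float, c3: float, c1: float) -> "SigmoidParams":
        """Sigmoid passing exactly through (r0, r0).

        Used to build ground-truth afferents whose resting discharge is
        self-consistent: with zero head motion the drive is r0 and the output
        firing rate is also r0.  Requires 0 < r0 < c3.
        """
        if not 0 < r0 < c3:
            raise ValueError("need 0 < r0 < c3 for a self-consistent resting point")
        c2 = r0 - np.sqrt(2.0 * c1) * erfinv(2.0 * r0 / c3 - 1.0)
        return cls(c1=c1, c2=float(c2), c3=c3)

    @classmethod
    def with_unit_gain_resting(cls, r0: float, c3: float) -> "SigmoidParams":
        """Sigmoid through (r0, r0) with unit slope there.

        The natural convention for a ground-truth afferent: around rest the
        sigmoid passes the linear drive through unchanged (gain 1), so the
        linear-stage gain keeps its meaning and the sigmoid contributes only
        the cutoff and saturation bends.  This also pins the scale split
        between the linear stage and the static nonlinearity, which a pure
        input-output fit cannot identify.  Requires 0 < r0 < c3.
        """
        if not 0 < r0 < c3:
            raise ValueError("need 0 < r0 < c3 for a self-consistent resting point")
        u = float(erfinv(2.0 * r0 / c3 - 1.0))
        sqrt_c1 = c3 / np.sqrt(2.0 * np.pi) * np.exp(-u * u)
        c2 = r0 - np.sqrt(2.0) * sqrt_c1 * u
        return cls(c1=float(sqrt_c1**2), c2=float(c2), c3=c3)


@dataclass
class BinnedTuning:
    """Firing rate averaged within narrow stimulus bins."""

    bin_edges: np.ndarray
    bin_centers: np.ndarray
    mean_rate: np.ndarray
    count: np.ndarray


@dataclass
class LNModel:
    """Fitted LN cascade for one afferent in one condition."""

    st: float
    r0: float
    lead_s: float
    sigmoid: SigmoidParams
    bias: float
    modulation_slope: float
    vaf_ln: float
    vaf_linear: float
    organ: str = "otolith"
    tuning: BinnedTuning | None = field(default=None, repr=False)

    def predict(self, channel: np.ndarray, fs: float) -> np.ndarray:
        """N(t) = Tsig(St * H(t + lead) + r0); bounded in [0, c3]."""
        h = advance(np.asarray(channel, float), int(round(self.lead_s * fs)))
        return self.sigmoid(self.st * h + self.r0)


def estimate_response_lag(
    rate: np.ndarray,
    channels: np.ndarray | tuple[np.ndarray, ...],
    fs: float,
    max_lag_s: float = 0.05,
) -> float:
    """Response lead (s) maximizing rate–stimulus correlation.

    For a single channel this is the cross-correlation peak within
    ``±max_lag_s``.  When a tuple of channels is given (the two-regressor
    linear models) the lag maximizes the R² of the joint least-squares fit,
    the multi-channel generalization of the cross-correlation.  Positive lead
    means firing precedes the motion, i.e. the stimulus must be advanced by
    the lead to align with the rate.
    """
    rate = np.asarray(rate, dtype=float)
    if isinstance(channels, np.ndarray):
        channels = (channels,)
    channels = tuple(np.asarray(c, dtype=float) for c in channels)
    if any(c.shape != rate.shape for c in channels):
        raise ValueError("rate and stimulus channels must share a grid")
    if np.std(rate) == 0:
        raise ValueError("flat firing rate: response lag undefined")
    if all(np.std(c) == 0 for c in channels):
        raise ValueError("flat stimulus: response lag undefined")

    max_lag = int(round(max_lag_s * fs))
    y = rate - rate.mean()
    ss_tot = float(y @ y)
    best_lag, best_r2 = 0, -np.inf
    for lag in range(-max_lag, max_lag + 1):
        cols = []
        for c in channels:
            a = advance(c, lag)
            a = a - a.mean()
            cols.append(a)
        x = np.column_stack(cols)
        coef, *_ = np.linalg.lstsq(x, y, rcond=None)
        resid = y - x @ coef
        r2 = 1.0 - float(resid @ resid) / ss_tot
        if r2 > best_r2:
            best_r2, best_lag = r2, lag
    return best_lag / fs


def determine_linear_range(channel: np.ndarray) -> np.ndarray:
    """Mask of samples with stimulus within mean ± 1 SD (the quasi-linear core)."""
    channel = np.asarray(channel, dtype=float)
    sd = channel.std()
    if sd == 0:
        raise ValueError("zero-variance stimulus: linear range undefined")
    return np.abs(channel - channel.mean()) <= sd


def fit_linear_stage(
    rate: np.ndarray, channel: np.ndarray, mask: np.ndarray
) -> tuple[float, float]:
    """Least squares of rate on one aligned stimulus channel: (St, r0)."""
    rate = np.asarray(rate, float)
    channel = np.asarray(channel, float)
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("empty linear-range mask")
    x, y = channel[mask], rate[mask]
    if x.std() == 0:
        raise ValueError("degenerate design: masked stimulus has zero variance")
    a = np.column_stack([x, np.ones_like(x)])
    (st, r0), *_ = np.linalg.lstsq(a, y, rcond=None)
    return float(st), float(r0)


def bin_stimulus_response(
    rate: np.ndarray, channel: np.ndarray, bin_width: float
) -> BinnedTuning:
    """Average the firing rate within fixed-width stimulus bins.

    Bin edges are integer multiples of ``bin_width`` so the default otolith
    binning lands on 0.0004 g boundaries.  Empty bins are dropped.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    rate = np.asarray(rate, float)
    channel = np.asarray(channel, float)
    if rate.size == 0 or channel.size == 0:
        raise ValueError("empty input")
    lo = np.floor(channel.min() / bin_width)
    hi = np.ceil(channel.max() / bin_width)
    edges = np.arange(lo, hi + 1) * bin_width
    if edges.size < 2:
        edges = np.array([lo * bin_width, (lo + 1) * bin_width])
    idx = np.clip(np.digitize(channel, edges) - 1, 0, edges.size - 2)
    count = np.bincount(idx, minlength=edges.size - 1)
    sums = np.bincount(idx, weights=rate, minlength=edges.size - 1)
    keep = count > 0
    centers = 0.5 * (edges[:-1] + edges[1:])
    return BinnedTuning(
        bin_edges=edges,
        bin_centers=centers[keep],
        mean_rate=sums[keep] / count[keep],
        count=count[keep],
    )


def fit_sigmoid(
    x: np.ndarray,
    y: np.ndarray,
    weights: np.ndarray | None = None,
    maxfev: int = 20000,
) -> SigmoidParams:
    """Nonlinear least squares of the erf sigmoid Tsig to (x, y) pairs.

    Initialization: c3 = max observed rate, c2 = x at half-max (interpolated),
    c1 = (x-range / 4)²; bounds keep c1, c3 positive.  Deterministic (single
    start).  ``weights`` are per-point weights (e.g. bin occupancy counts).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 4:
        raise ValueError("need at least 4 points to fit the sigmoid")
    if np.ptp(y) <= 0:
        raise ValueError("response has no dynamic range")
    c3_0 = float(y.max())
    half = 0.5 * c3_0
    order = np.argsort(x)
    xs, ys = x[order], y[order]
    above = np.nonzero(ys >= half)[0]
    c2_0 = float(xs[above[0]]) if above.size else float(np.median(xs))
    c1_0 = max((np.ptp(x) / 4.0) ** 2, 1e-12)
    sigma = None
    if weights is not None:
        w = np.asarray(weights, float)
        sigma = 1.0 / np.sqrt(np.maximum(w, 1e-12))

    def model(xx, c1, c2, c3):
        return 0.5 * c3 * (1.0 + erf((xx - c2) / np.sqrt(2.0 * np.abs(c1))))

    lo = [1e-12, -np.inf, 1e-9]
    hi = [np.inf, np.inf, np.inf]
    popt, _ = curve_fit(
        model,
        x,
        y,
        p0=[c1_0, c2_0, c3_0],
        sigma=sigma,
        bounds=(lo, hi),
        maxfev=maxfev,
        xtol=1e-8,
        ftol=1e-8,
    )
    return SigmoidParams(c1=float(popt[0]), c2=float(popt[1]), c3=float(popt[2]))


def _vaf(observed: np.ndarray, predicted: np.ndarray) -> float:
    observed = np.asarray(observed, float)
    v = observed.var()
    if v == 0:
        raise ValueError("zero-variance observed signal")
    return 1.0 - float(np.var(observed - np.asarray(predicted, float))) / float(v)


def fit_ln_model(
    rate: np.ndarray,
    channel: np.ndarray,
    fs: float,
    organ: str = "otolith",
    bin_width: float | None = None,
    max_lag_s: float = 0.05,
) -> LNModel:
    """Fit the full LN cascade to one afferent recording.

    ``channel`` is the organ's primary head-motion channel on the same grid as
    ``rate``.  The default bin width is 0.0004 g for otolith acceleration; for
    canal velocity channels (where the stimulus is in deg/s) it defaults to
    SD/50, preserving comparable bin occupancy.
    """
    rate = np.asarray(rate, float)
    channel = np.asarray(channel, float)
    lead = estimate_response_lag(rate, channel, fs, max_lag_s=max_lag_s)
    aligned = advance(channel, int(round(lead * fs)))

    mask = determine_linear_range(aligned)
    st, r0 = fit_linear_stage(rate, aligned, mask)

    if bin_width is None:
        bin_width = (
            DEFAULT_OTOLITH_BIN_G if organ == "otolith" else float(aligned.std()) / 50.0
        )
    tuning = bin_stimulus_response(rate, aligned, bin_width)
    # express the tuning against the linear prediction (Eq 5 output)
    z_centers = st * tuning.bin_centers + r0
    sigmoid = fit_sigmoid(z_centers, tuning.mean_rate, weights=tuning.count)

    z = st * aligned + r0
    vaf_ln = _vaf(rate, sigmoid(z))
    vaf_linear = _vaf(rate, z)
    return LNModel(
        st=st,
        r0=r0,
        lead_s=lead,
        sigmoid=sigmoid,
        bias=float(sigmoid(r0)),
        modulation_slope=float(st * sigmoid.slope(r0)),
        vaf_ln=vaf_ln,
        vaf_linear=vaf_linear,
        organ=organ,
        tuning=tuning,
    )
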