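"""Least-squares linear rate models of vestibular afferent responses.

Canal afferents are modeled as

    fr(t) = b + Sv * Hdot(t) + Sa * Hddot(t)          (velocity, acceleration)

and otolith afferents as

    fr(t) = b + Sa * Hddot(t) + Sj * Hdddot(t)        (acceleration, jerk)

where the motion channels are advanced by the neuron's response lead before
fitting and the fit is restricted to samples with firing rate above
``min_rate`` (default 10 sp/s) so that epochs potentially driven into
inhibitory cutoff do not bias the coefficients.  The frequency-resolved
response modulation follows from the coefficient pair:

    St(f) = sqrt(S1^2 + (2 pi f S2)^2)

in (sp/s)/(deg/s) for canal and (sp/s)/g for otolith afferents.  VAF
(variance accounted for) and VIF (variance inflation factor) quantify fit
quality and regressor collinearity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._signal import advance
from .ln_cascade import estimate_response_lag
from .spike_processing import RateTrace
from .synthetic import StimulusTrace

__all__ = [
    "LinearRateModel",
    "fit_linear_rate_model",
    "gain_at_frequency",
    "predict_rate",
    "model_diagnostics",
    "ORGAN_CHANNELS",
    "DEFAULT_MIN_RATE",
]

#: Motion channels entering each organ's design matrix, in coefficient order.
ORGAN_CHANNELS = {
    "canal": ("pitch_velocity", "pitch_acceleration"),
    "otolith": ("linear_acceleration", "jerk"),
}
DEFAULT_MIN_RATE = 10.0
#: VIF above this raises a multicollinearity error.
VIF_BOUND = 10.0


@dataclass
class LinearRateModel:
    """Fitted two-channel linear rate model for one afferent."""

    organ: str
    bias: float
    coef1: float  # Sv (canal) or Sa (otolith)
    coef2: float  # Sa (canal) or Sj (otolith)
    lead_s: float
    fit_mask: np.ndarray = field(repr=False)
    vaf: float = float("nan")
    vif: tuple[float, float] = (float("nan"), float("nan"))
    residual_slope: float = float("nan")
    n_used: int = 0


def _design(stim: StimulusTrace, organ: str, lead_s: float) -> np.ndarray:
    if organ not in ORGAN_CHANNELS:
        raise ValueError(f"unknown organ {organ!r}")
    m = int(round(lead_s * stim.sample_rate))
    cols = [advance(stim.channel(name), m) for name in ORGAN_CHANNELS[organ]]
    return np.column_stack(cols)


def fit_linear_rate_model(
    rate: RateTrace,
    stim: StimulusTrace,
    organ: str,
    min_rate: float = DEFAULT_MIN_RATE,
    lead_s: float | None = 0.0,
    max_lag_s: float = 0.05,
    mask_on: str = "prediction",
    design_smoothing_hz: float | None = None,
) -> LinearRateModel:
    """Ordinary least squares of the firing rate on the organ's channels.

    The stimulus is advanced by ``lead_s`` before fitting and samples with
    rate > ``min_rate`` after alignment enter the fit.  With the default
    ``mask_on="prediction"`` the low-rate exclusion is refined on the fitted
    model's prediction (two passes): truncating on the noisy rate estimate
    itself preferentially drops samples with negative estimation noise and
    attenuates the coefficients, whereas truncating on the prediction is
    selection on the regressors only and leaves the fit unbiased.
    ``mask_on="observed"`` reproduces the literal mask on the measured rate.

    The default lead is zero because the derivative regressor already
    encodes the response phase: the (velocity, acceleration) — or
    (acceleration, jerk) — pair spans both quadratures, so under narrowband
    stimulation a time shift and a coefficient rotation are interchangeable
    and a jointly estimated lag is not identifiable.  Passing
    ``lead_s=None`` estimates the lag anyway (R²-maximizing joint shift over
    both channels), which is meaningful for broadband stimuli.

    ``design_smoothing_hz`` low-passes the motion regressors with the
    Kaiser kernel used for rate estimation at that cutoff, so both sides of
    the regression see identical filtering and the coefficients stay
    unbiased even for channels with power near the kernel corner.  Pass the
    rate estimator's cutoff when ``rate`` came from
    :func:`~vestenc.spike_processing.estimate_firing_rate`; the default
    ``None`` fits on the raw channels (exact for noise-free rates).
    """
    y = np.asarray(rate.rate, dtype=float)
    if y.shape != stim.t.shape:
        raise ValueError("rate and stimulus must share a grid")
    names = ORGAN_CHANNELS[organ]
    if lead_s is None:
        lead_s = estimate_response_lag(
            y,
            tuple(stim.channel(nm) for nm in names),
            stim.sample_rate,
            max_lag_s=max_lag_s,
        )
    if mask_on not in ("prediction", "observed"):
        raise ValueError("mask_on must be 'prediction' or 'observed'")
    x = _design(stim, organ, lead_s)
    if design_smoothing_hz is not None:
        from scipy.signal import fftconvolve

        from .spike_processing import kaiser_rate_kernel

        kern = kaiser_rate_kernel(stim.sample_rate, design_smoothing_hz)
        x = np.column_stack(
            [fftconvolve(x[:, j], kern, mode="same") for j in range(x.shape[1])]
        )
    mask = y > min_rate
    n_pass = 3 if mask_on == "prediction" else 1
    for _ in range(n_pass):
        if mask.sum() < 10:
            raise ValueError(
                f"too few samples above {min_rate} sp/s for a well-posed fit"
            )
        xm, ym = x[mask], y[mask]
        sds = xm.std(axis=0)
        if np.any(sds == 0):
            raise ValueError("degenerate design: zero-variance regressor")
        a = np.column_stack([np.ones(mask.sum()), xm])
        coef, *_ = np.linalg.lstsq(a, ym, rcond=None)
        if mask_on == "prediction":
            full_pred = coef[0] + x @ coef[1:]
            new_mask = full_pred > min_rate
            if np.array_equal(new_mask, mask):
                break
            mask = new_mask
    pred = a @ coef
    diag = model_diagnostics(ym, pred, design=xm)
    if max(diag["vif"]) > VIF_BOUND:
        raise ValueError(
            f"severe multicollinearity: VIF {max(diag['vif']):.1f} > {VIF_BOUND}"
        )
    resid = ym - pred
    # residual-vs-fit diagnostic: slope of residuals on fitted values
    pc = pred - pred.mean()
    res_slope = float(pc @ resid / (pc @ pc)) if pc.any() else float("nan")
    return LinearRateModel(
        organ=organ,
        bias=float(coef[0]),
        coef1=float(coef[1]),
        coef2=float(coef[2]),
        lead_s=float(lead_s),
        fit_mask=mask,
        vaf=diag["vaf"],
        vif=tuple(diag["vif"]),
        residual_slope=res_slope,
        n_used=int(mask.sum()),
    )


def gain_at_frequency(model: LinearRateModel, f: float) -> float:
    """Response modulation St at stimulus frequency f (Hz).

    St = sqrt(S1² + (2 pi f S2)²): (sp/s)/(deg/s) for canal afferents,
    (sp/s)/g for otolith afferents.
    """
    if f < 0:
        raise ValueError("frequency must be non-negative")
    return float(np.hypot(model.coef1, 2.0 * np.pi * f * model.coef2))


def predict_rate(
    model: LinearRateModel, stim: StimulusTrace, rectify: bool = False
) -> np.ndarray:
    """Linear prediction b + S1*ch1 + S2*ch2 on the lead-advanced stimulus.

    With ``rectify`` off the raw prediction may go negative — exactly the
    physiologically impossible regime used to diagnose inhibitory cutoff;
    with it on, the prediction is clipped at zero.
    """
    x = _design(stim, model.organ, model.lead_s)
    pred = model.bias + x @ np.array([model.coef1, model.coef2])
    return np.maximum(pred, 0.0) if rectify else pred


def model_diagnostics(
    observed: np.ndarray,
    predicted: np.ndarray,
    design: np.ndarray | None = None,
) -> dict:
    """VAF of a prediction and per-regressor VIFs of a design matrix.

    VAF = 1 - var(observed - predicted) / var(observed).  VIF_j =
    1 / (1 - R²_j) where R²_j is from regressing column j on the others
    (with intercept); requires >= 2 design columns.
    """
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.shape != predicted.shape:
        raise ValueError("observed and predicted must have equal length")
    vo = observed.var()
    if vo == 0:
        raise ValueError("zero-variance observed signal")
    vaf = 1.0 - float(np.var(observed - predicted)) / float(vo)
    out = {"vaf": vaf, "vif": []}
    if design is not None:
        design = np.asarray(design, dtype=float)
        if design.ndim != 2 or design.shape[1] < 2:
            raise ValueError("VIF needs a design matrix with >= 2 regressors")
        for j in range(design.shape[1]):
            others = np.column_stack(
                [np.ones(design.shape[0])]
                + [design[:, k] for k in range(design.shape[1]) if k != j]
            )
            yj = design[:, j]
            coef, *_ = np.linalg.lstsq(others, yj, rcond=None)
            resid = yj - others @ coef
            denom = ((yj - yj.mean()) ** 2).sum()
            r2 = 1.0 - float((resid**2).sum()) / float(denom) if denom else 0.0
            out["vif"].append(1.0 / max(1.0 - r2, 1e-12))
    return out
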