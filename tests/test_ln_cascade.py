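"""LN cascade: sigmoid identities, staging operations, and composite fits."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vestenc.ln_cascade import (
    SigmoidParams,
    bin_stimulus_response,
    determine_linear_range,
    estimate_response_lag,
    fit_linear_stage,
    fit_ln_model,
    fit_sigmoid,
)

FS = 1000.0


# -------------------------------------------------------------- sigmoid shape


@given(
    c1=st.floats(min_value=1e-3, max_value=1e4),
    c2=st.floats(min_value=-100, max_value=100),
    c3=st.floats(min_value=1.0, max_value=500.0),
)
@settings(max_examples=50, deadline=None)
def test_sigmoid_inflection_and_asymptotes(c1, c2, c3):
    sig = SigmoidParams(c1, c2, c3)
    assert sig(c2) == pytest.approx(c3 / 2, rel=1e-9)
    assert sig(c2 - 100 * np.sqrt(c1)) == pytest.approx(0.0, abs=1e-9 * c3)
    assert sig(c2 + 100 * np.sqrt(c1)) == pytest.approx(c3, rel=1e-9)
    x = np.linspace(c2 - 5 * np.sqrt(c1), c2 + 5 * np.sqrt(c1), 101)
    y = sig(x)
    assert np.all(y >= 0) and np.all(y <= c3)
    assert np.all(np.diff(y) >= 0)


def test_sigmoid_requires_positive_width_and_ceiling():
    with pytest.raises(ValueError):
        SigmoidParams(-1.0, 0.0, 10.0)
    with pytest.raises(ValueError):
        SigmoidParams(1.0, 0.0, 0.0)


def test_unit_gain_resting_construction():
    sig = SigmoidParams.with_unit_gain_resting(75.0, 225.0)
    assert sig(75.0) == pytest.approx(75.0, rel=1e-9)
    assert sig.slope(75.0) == pytest.approx(1.0, rel=1e-9)
    # asymmetric operating point: more headroom above than below
    assert sig.c2 > 75.0


# ------------------------------------------------------------- lag estimation


def test_lag_zero_for_proportional_signals(rng):
    x = rng.standard_normal(20000)
    assert estimate_response_lag(3.0 * x + 5.0, x, FS) == 0.0


def test_constructed_lead_recovered(rng):
    from scipy.ndimage import gaussian_filter1d

    x = gaussian_filter1d(rng.standard_normal(60000), 25.0)
    shift = 12
    rate = np.roll(x, -shift)  # firing precedes the stimulus by 12 ms
    lead = estimate_response_lag(rate[100:-100], x[100:-100], FS)
    assert lead * 1000 == pytest.approx(12.0, abs=1.0)


def test_flat_inputs_raise(rng):
    x = rng.standard_normal(1000)
    with pytest.raises(ValueError):
        estimate_response_lag(np.ones(1000), x, FS)
    with pytest.raises(ValueError):
        estimate_response_lag(x, np.ones(1000), FS)


# -------------------------------------------------------------- linear range


def test_linear_range_gaussian_fraction(rng):
    x = rng.standard_normal(200000)
    frac = determine_linear_range(x).mean()
    assert frac == pytest.approx(0.683, abs=0.01)


def test_linear_range_uniform_bound(rng):
    x = rng.uniform(-1, 1, size=200000)
    mask = determine_linear_range(x)
    # SD of U(-1,1) is 1/sqrt(3); mask keeps |x| <= 1/sqrt(3)
    assert np.abs(x[mask]).max() <= 1 / np.sqrt(3) + 0.01
    assert frac_close(mask.mean(), 1 / np.sqrt(3))


def frac_close(value, expected):
    return abs(value - expected) < 0.01


def test_linear_range_constant_raises():
    with pytest.raises(ValueError):
        determine_linear_range(np.ones(100))


# -------------------------------------------------------------- linear stage


def test_linear_stage_exact_on_noiseless_data(rng):
    x = rng.standard_normal(5000)
    rate = 0.9 * x + 70.0
    mask = determine_linear_range(x)
    st_, r0 = fit_linear_stage(rate, x, mask)
    assert st_ == pytest.approx(0.9, rel=1e-9)
    assert r0 == pytest.approx(70.0, rel=1e-9)


def test_linear_stage_zero_slope(rng):
    x = rng.standard_normal(5000)
    rate = np.full_like(x, 42.0)
    st_, r0 = fit_linear_stage(rate, x, np.ones_like(x, dtype=bool))
    assert st_ == pytest.approx(0.0, abs=1e-9)
    assert r0 == pytest.approx(42.0)


def test_linear_stage_mask_excludes_cutoff_region(rng):
    """Masking out the clipped region reproduces the unclipped fit."""
    x = rng.standard_normal(50000)
    raw = 30.0 * x + 40.0
    clipped = np.maximum(raw, 0.0)
    mask = x > -1.0  # clipping happens below x = -4/3
    st_c, r0_c = fit_linear_stage(clipped, x, mask)
    st_u, r0_u = fit_linear_stage(raw, x, mask)
    assert st_c == pytest.approx(st_u, rel=1e-6)
    assert r0_c == pytest.approx(r0_u, rel=1e-6)


def test_linear_stage_empty_mask_raises(rng):
    x = rng.standard_normal(100)
    with pytest.raises(ValueError):
        fit_linear_stage(x, x, np.zeros_like(x, dtype=bool))


# -------------------------------------------------------------------- binning


def test_two_bin_hand_example():
    rate = np.array([20.0, 40.0, 60.0])
    x = np.array([-0.01, -0.01, 0.01])
    tuning = bin_stimulus_response(rate, x, bin_width=0.02)
    assert np.array_equal(tuning.count, [2, 1])
    assert np.allclose(tuning.mean_rate, [30.0, 60.0])


def test_single_bin_mean():
    rate = np.array([10.0, 20.0, 30.0])
    x = np.array([0.0001, 0.0002, 0.0003])
    tuning = bin_stimulus_response(rate, x, bin_width=0.0004)
    assert tuning.count.sum() == 3
    assert tuning.mean_rate[0] == pytest.approx(20.0)


def test_default_bin_edges_are_multiples_of_bin_width(rng):
    x = rng.normal(0, 0.05, size=10000)
    tuning = bin_stimulus_response(rng.normal(80, 5, size=10000), x, 0.0004)
    ratios = tuning.bin_edges / 0.0004
    assert np.allclose(ratios, np.round(ratios), atol=1e-9)
    assert tuning.count.sum() == 10000


def test_binning_rejects_bad_input():
    with pytest.raises(ValueError):
        bin_stimulus_response(np.array([1.0]), np.array([0.0]), 0.0)
    with pytest.raises(ValueError):
        bin_stimulus_response(np.array([]), np.array([]), 0.0004)


# ------------------------------------------------------------------- sigmoid


def test_sigmoid_fit_recovers_generating_parameters(rng):
    truth = SigmoidParams(c1=400.0, c2=50.0, c3=120.0)
    x = np.linspace(-20, 120, 60)
    y = truth(x) + rng.normal(0, 1.0, x.size)
    fit = fit_sigmoid(x, y)
    assert fit.c1 == pytest.approx(400.0, rel=0.1)
    assert fit.c2 == pytest.approx(50.0, rel=0.1)
    assert fit.c3 == pytest.approx(120.0, rel=0.1)


def test_sigmoid_fit_requires_informative_data(rng):
    with pytest.raises(ValueError):
        fit_sigmoid(np.arange(3.0), np.arange(3.0))
    with pytest.raises(ValueError):
        fit_sigmoid(np.arange(10.0), np.full(10, 5.0))


# ------------------------------------------------------------- composite fit


def test_ln_model_composite_on_synthetic_cascade(rng):
    """Full staging on a clean simulated cascade; bias/modulation identities."""
    from scipy.ndimage import gaussian_filter1d

    x = gaussian_filter1d(rng.standard_normal(240000), 40.0)
    x *= 0.08 / x.std()
    truth_sig = SigmoidParams.with_unit_gain_resting(70.0, 210.0)
    st_true = 400.0
    rate = truth_sig(st_true * np.roll(x, -10) + 70.0)
    ln = fit_ln_model(rate[200:-200], x[200:-200], FS, organ="otolith")
    assert ln.lead_s * 1000 == pytest.approx(10.0, abs=1.0)
    assert ln.r0 == pytest.approx(70.0, rel=0.05)
    assert ln.st == pytest.approx(st_true, rel=0.08)
    # identities: bias and modulation evaluated at the zero-motion point
    assert ln.bias == pytest.approx(ln.sigmoid(ln.r0), rel=1e-9)
    assert ln.modulation_slope == pytest.approx(
        ln.st * ln.sigmoid.slope(ln.r0), rel=1e-9
    )
    assert ln.bias == pytest.approx(70.0, rel=0.05)
    assert ln.vaf_ln >= ln.vaf_linear - 1e-9
    # the LN prediction respects the sigmoid's physical bounds
    pred = ln.predict(x, FS)
    assert pred.min() >= 0.0 and pred.max() <= ln.sigmoid.c3 + 1e-9


def test_ln_prediction_never_negative_even_when_linear_is(rng):
    from scipy.ndimage import gaussian_filter1d

    x = gaussian_filter1d(rng.standard_normal(120000), 30.0)
    x *= 0.2 / x.std()
    rate = np.maximum(60.0 + 500.0 * x, 0.0)
    ln = fit_ln_model(rate, x, FS, organ="otolith")
    linear_pred = ln.st * x + ln.r0
    assert linear_pred.min() < 0.0
    assert ln.predict(x, FS).min() >= 0.0
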