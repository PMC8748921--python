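"""Shared fixtures: moderate-length stimuli and a small synthetic cohort.

Everything is generated programmatically with fixed seeds; session scope
keeps the expensive traces shared across test modules.
"""

from __future__ import annotations

import numpy as np
import pytest

from vestenc.synthetic import (
    AfferentGroundTruth,
    CohortConfig,
    StimulusParams,
    generate_cohort,
    generate_stimulus,
)

FS = 1000.0


@pytest.fixture(scope="session")
def params() -> StimulusParams:
    return StimulusParams()


@pytest.fixture(scope="session")
def passive_low_120s():
    return generate_stimulus("passive_low", 120.0, seed=101)


@pytest.fixture(scope="session")
def walking_120s():
    return generate_stimulus("walking", 120.0, seed=102)


@pytest.fixture(scope="session")
def running_120s():
    return generate_stimulus("running", 120.0, seed=103)


@pytest.fixture(scope="session")
def linear_canal_truth() -> AfferentGroundTruth:
    return AfferentGroundTruth(
        organ="canal",
        regularity="regular",
        resting_rate=90.0,
        response_lead_s=0.0,
        isi_shape=100.0,
        sv=0.4,
        sa=0.02,
    )


@pytest.fixture(scope="session")
def small_cohort():
    counts = {
        ("canal", "regular"): 2,
        ("canal", "irregular"): 2,
        ("otolith", "regular"): 2,
        ("otolith", "irregular"): 3,
    }
    cfg = CohortConfig(counts=counts, duration_s=60.0, resting_duration_s=20.0)
    return generate_cohort(cfg, seed=3)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
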