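import matplotlib

matplotlib.use("Agg")

import math

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from icgpv import SyntheticTruth, simulate_study

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

#: Nominal post-injection draw schedule (seconds).
DRAW_SCHEDULE_S = (120.0, 165.0, 210.0, 255.0, 300.0)


@pytest.fixture
def exact_decay_samples():
    """Noise-free mono-exponential draws: C(t) = 8 exp(-0.25 t / 60)."""
    return [(t, 8.0 * math.exp(-0.25 * t / 60.0)) for t in DRAW_SCHEDULE_S]


@pytest.fixture
def clean_truth():
    """A ground truth with every noise source switched off."""
    return SyntheticTruth(
        participant_id="P01",
        true_pv_l=2.0,
        true_k_per_min=0.25,
        dose_mg=16.0,
        mixing_tau_s=0.0,
        absorbance_noise_sd=0.0,
        standard_prep_cv=0.0,
        timing_jitter_sd_s=0.0,
        rng_seed=11,
    )


@pytest.fixture(scope="session")
def noise_free_study():
    """A 3-subject study that must round-trip to machine precision."""
    return simulate_study(
        n=3,
        seed=202,
        absorbance_noise_sd=0.0,
        standard_prep_cv=0.0,
        timing_jitter_sd_s=0.0,
        mixing_tau_s=0.0,
    )


@pytest.fixture(scope="session")
def default_noise_study():
    """A 9-subject study at the default noise/mixing settings."""
    return simulate_study(n=9, seed=31)
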