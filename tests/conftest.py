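import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import specklight as sl

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_model() -> sl.TrainedRegressor:
    """A quickly trained ML-DCS model shared across tests.

    2000 training windows is enough for stable lesion/background ordering
    and the shrinkage behaviour the map-level tests exercise.
    """
    cfg = sl.TrainingConfig(n_train=2000, max_epochs=40, seed=7)
    return sl.train_regressor(sl.generate_training_set(cfg), cfg)


@pytest.fixture(scope="session")
def lesion_stack_60s():
    """Standard lesion phantom, 64x64, 60 s at 100 fps (noiseless).

    Tumour (0.67 s) and mirrored-control (0.39 s background) ROIs each hold
    over 1000 pixels.
    """
    spec = sl.standard_lesion_phantom(seed=11)
    stack, gt = sl.simulate_stack(spec)
    return stack, gt


@pytest.fixture(scope="session")
def lesion_stack_small():
    """A faster 24x24, 20 s lesion phantom for unit-level ROI checks."""
    spec = sl.standard_lesion_phantom(height=24, width=24, n_frames=2000, seed=3)
    stack, gt = sl.simulate_stack(spec)
    return stack, gt


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
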