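import numpy as np
import pytest

from vpcoupling.synthetic import GenerativePreset, default_presets


@pytest.fixture(scope="session")
def young_preset() -> GenerativePreset:
    return default_presets()["young"]


@pytest.fixture(scope="session")
def older_preset() -> GenerativePreset:
    return default_presets()["older"]


@pytest.fixture
def noiseless_preset() -> GenerativePreset:
    """Degenerate preset: all noise off, no sequential modulation, no outliers."""
    return GenerativePreset(
        group="young",
        n_participants=2,
        slope_hand_explicit=0.63,
        slope_cursor_explicit=-0.08,
        slope_hand_implicit=0.31,
        intercept_hand_explicit=0.0,
        sd_hand_explicit=0.0,
        sd_cursor_explicit=0.0,
        sd_implicit=0.0,
        motor_sd=0.0,
        return_length_cv=0.0,
        seq_delta_explicit_same=0.0,
        seq_delta_implicit_after_hand=0.0,
        outlier_rate=0.0,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    """Fresh seeded generator per test, so results don't depend on test order."""
    return np.random.default_rng(20130719)
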