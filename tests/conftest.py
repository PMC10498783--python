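import numpy as np
import pytest

from zoneassay.simulate import SimConfig, simulate_timelapse


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """Scaled-down well (1.5 mm zone) for fast rendering in unit tests."""
    return SimConfig(
        zone_diameter_mm=1.5,
        image_margin_mm=0.4,
        duration_h=24.0,
        frame_interval_h=3.0,
        front_velocity_um_per_h=10.0,
        rng_seed=11,
    )


@pytest.fixture(scope="session")
def small_series(small_config):
    """One small simulated series plus its ground truth, shared read-only."""
    return simulate_timelapse(small_config, keep_masks=True)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
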