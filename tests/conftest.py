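import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import pavactin as pv

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_movie():
    """A short noisy turnover movie reused across tests."""
    params = pv.FilamentSimParams(
        width_px=96, height_px=96, n_frames=30, n_filaments=25,
        turnover_rate_per_s=0.05, seed=11,
    )
    stack, truth = pv.simulate_filament_movie(params)
    return stack, truth


@pytest.fixture(scope="session")
def lobed_mosaic():
    params = pv.LobedCellParams(
        n_cells=9, base_radius_um=15.0, lobe_count=5, lobe_amplitude=0.3,
        pixel_size_um=0.5, seed=21,
    )
    mask, truth = pv.generate_lobed_cells(params)
    return mask, truth
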