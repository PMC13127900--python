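import numpy as np
import pytest

from uterodyn.core import GridGeometry
from uterodyn.phantom import EventSpec, ScenarioConfig, simulate_session

TUKEY = {"profile": "tukey", "profile_params": {"taper_fraction": 0.25}}

# compact geometry: ~3x faster to simulate/measure than the full-size default
SMALL_GEOMETRY = dict(
    grid_shape=(64, 64, 18),
    uterus_semiaxes_mm=(55.0, 48.0, 42.0),
    wall_thickness_mm=10.0,
    placenta_thickness_mm=20.0,
)


def make_config(**overrides) -> ScenarioConfig:
    kwargs = dict(SMALL_GEOMETRY)
    kwargs.update(overrides)
    return ScenarioConfig(**kwargs)


@pytest.fixture(scope="session")
def default_grid() -> GridGeometry:
    return GridGeometry(shape=(96, 96, 24))


@pytest.fixture(scope="session")
def small_session():
    """One noisy session with a placental and a uterine event plus motion."""
    config = make_config(
        n_frames=70,
        events=(
            EventSpec("placental", 180.0, 240.0, 0.2, **TUKEY),
            EventSpec("uterine_uniform", 620.0, 220.0, 0.15, **TUKEY),
        ),
        noise_sd_fraction=0.02,
        motion_events=((8, "maternal", 10.0), (62, "fetal", 1.0)),
        rng_seed=11,
    )
    series, ground_truth = simulate_session(config)
    return config, series, ground_truth


@pytest.fixture(scope="session")
def quiet_session():
    """Noise-free, motion-free, event-free session (3 frames)."""
    config = make_config(n_frames=3)
    series, ground_truth = simulate_session(config)
    return config, series, ground_truth


def digitized_ball(grid: GridGeometry, radius_mm: float) -> np.ndarray:
    from uterodyn.phantom import rasterize_to_slices

    def label_fn(points):
        return (np.sum(points**2, axis=-1) <= radius_mm**2).astype(np.uint8)

    return rasterize_to_slices(label_fn, grid)
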