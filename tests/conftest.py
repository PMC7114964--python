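import numpy as np
import pytest

from reefmounds import (
    Grid,
    MoundSpec,
    SyntheticSceneConfig,
    compute_bpi,
    delineate,
    generate_dem,
)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def flat_grid():
    """Horizontal seabed at 150 m depth."""
    return Grid(np.full((40, 40), -150.0), cell_size=2.0)


@pytest.fixture()
def ramp_grid():
    """Plane rising 1 m per metre eastwards (45 degree slope)."""
    x = (np.arange(30) + 0.5) * 2.0
    return Grid(np.tile(x, (30, 1)) - 150.0, cell_size=2.0)


def make_mound_grid(
    shape=(60, 60),
    cell=2.0,
    base=-150.0,
    height=8.0,
    sd=5.0,
    center=None,
    plane_slope_deg=0.0,
):
    """Single circular Gaussian mound on a (possibly sloping) plane."""
    nr, nc = shape
    xs = (np.arange(nc) + 0.5) * cell
    ys = (nr - np.arange(nr) - 0.5) * cell
    xx, yy = np.meshgrid(xs, ys)
    cx, cy = center or (nc * cell / 2, nr * cell / 2)
    z = base + np.tan(np.radians(plane_slope_deg)) * xx
    z = z + height * np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * sd**2))
    return Grid(z, cell, origin=(0.0, nr * cell))


@pytest.fixture()
def mound_grid():
    return make_mound_grid()


@pytest.fixture(scope="session")
def small_scene():
    """Compact scene: 6 well-separated planted mounds on a sloping plane."""
    mounds = [
        MoundSpec(80, 80, 8.0, 5.0, 4.0, azimuth_deg=30),
        MoundSpec(220, 90, 7.0, 4.5, 4.5),
        MoundSpec(330, 70, 9.0, 5.5, 3.5, azimuth_deg=120),
        MoundSpec(90, 250, 6.5, 4.0, 4.0),
        MoundSpec(230, 260, 8.5, 5.0, 3.0, azimuth_deg=75),
        MoundSpec(330, 250, 7.5, 4.5, 4.0, azimuth_deg=160),
    ]
    cfg = SyntheticSceneConfig(
        grid_shape=(170, 200),
        cell_size=2.0,
        base_depth=150.0,
        plane_slope_deg=1.0,
        plane_azimuth_deg=90.0,
        ridge=None,
        mounds=mounds,
        noise_sd=0.0,
        seed=7,
    )
    dem, registry = generate_dem(cfg)
    return cfg, dem, registry


@pytest.fixture(scope="session")
def small_scene_features(small_scene):
    cfg, dem, registry = small_scene
    bpi = compute_bpi(dem)
    features = delineate(bpi)
    return dem, bpi, features, registry
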