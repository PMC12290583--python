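import pytest

import metaconn as mc


@pytest.fixture(scope="session")
def small_grid():
    """4-mm ellipsoid fixture grid used throughout the desk-scale tests."""
    return mc.make_grid(4.0, (72.0, 72.0, 64.0),
                        {"type": "ellipsoid", "semi_axes_mm": [32.0, 32.0, 28.0]})


@pytest.fixture(scope="session")
def full_grid_10():
    """Tiny fully masked 10^3 grid for exact numerical oracles."""
    return mc.make_grid(4.0, (40.0, 40.0, 40.0), "full")


@pytest.fixture(scope="session")
def paper_world():
    return mc.gen_world_fixture("paper-like", 7)


@pytest.fixture(scope="session")
def tiny_world():
    return mc.gen_world_fixture("tiny", 11)


def random_ma_maps(grid, n_maps, rng, scale=0.1):
    """Random MA-like maps in [0, scale] on a grid."""
    return [
        mc.VolumeMap(grid, rng.uniform(0.0, scale, size=grid.shape), "MA")
        for _ in range(n_maps)
    ]
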