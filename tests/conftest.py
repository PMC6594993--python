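import numpy as np
import pytest

from neurosmc import (
    SimulationParams,
    generate_toy_tree,
    simulate,
    voxelize_partial_volume,
)


@pytest.fixture(scope="session")
def y_tree():
    """Y-shaped phantom: trunk plus two 45-degree arms, radius 2."""
    return generate_toy_tree("Y", length=48, radius=2, origin=(8, 32, 8))


@pytest.fixture(scope="session")
def y_volume_snr20(y_tree):
    params = SimulationParams(snr=20, cor=0, seed=3)
    return simulate(y_tree, (64, 64, 16), params).astype(float)


@pytest.fixture(scope="session")
def line_tree():
    """Straight radius-2 branch spanning x = 4..60 of a 64x24x24 volume."""
    return generate_toy_tree("line", length=56, radius=2, origin=(4, 12, 12))


@pytest.fixture(scope="session")
def line_occupancy(line_tree):
    return voxelize_partial_volume(line_tree, (64, 24, 24), SimulationParams())


@pytest.fixture(scope="session")
def line_volume_clean(line_occupancy):
    """Noise-free analog: the occupancy map itself scaled to 8-bit."""
    occ = line_occupancy
    return np.round(occ / occ.max() * 255.0)


@pytest.fixture(scope="session")
def line_volume_snr20(line_tree, line_occupancy):
    params = SimulationParams(snr=20, cor=0, seed=9)
    return simulate(line_tree, (64, 24, 24), params, occupancy=line_occupancy).astype(
        float
    )
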