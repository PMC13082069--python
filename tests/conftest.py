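import numpy as np
import pytest

from channelmd import (
    PoreAxis,
    RingSpec,
    Selection,
    ToyChannelSpec,
    Trajectory,
    make_toy_channel,
)


@pytest.fixture
def z_axis() -> PoreAxis:
    return PoreAxis((0.0, 0.0, 0.0), (0.0, 0.0, 1.0))


@pytest.fixture
def single_ring():
    """One 8-atom ring: exact on-axis pore radius 5.0 - 1.7 = 3.3 A."""
    return make_toy_channel(
        ToyChannelSpec(rings=[RingSpec(0.0, 5.0, 1.7, 8)])
    )


@pytest.fixture
def two_ring():
    return make_toy_channel(
        ToyChannelSpec(
            rings=[RingSpec(0.0, 5.0, 1.7, 8), RingSpec(10.0, 3.7, 1.7, 8)]
        )
    )


@pytest.fixture
def quad_toy():
    """Fourfold toy with one atom per subunit per ring (opposing pairs)."""
    return make_toy_channel(
        ToyChannelSpec(
            rings=[RingSpec(0.0, 4.0, 1.52, 4), RingSpec(12.0, 4.0, 1.52, 4)]
        )
    )


@pytest.fixture
def static_traj(quad_toy) -> Trajectory:
    coords = quad_toy.structure.coords()
    return Trajectory(quad_toy.structure, np.repeat(coords[None], 3, axis=0), 1.0)


@pytest.fixture
def all_atoms() -> Selection:
    return Selection()
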