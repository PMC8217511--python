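import numpy as np
import pytest

from cartwheel import geometry


@pytest.fixture
def ring_step():
    """Native head-to-head step: 40-degree bend, no rise."""
    return geometry.interface_step(40.0, 0.0)


@pytest.fixture
def helix_step():
    """Fourfold-helix step: 90-degree twist, 6.5 nm rise."""
    return geometry.interface_step(90.0, 6.5)


@pytest.fixture
def ring_assembly(ring_step):
    seed = geometry.default_seed_unit(step=ring_step)
    return geometry.propagate(seed, ring_step, 9)


@pytest.fixture
def helix_assembly(helix_step):
    seed = geometry.default_seed_unit(step=helix_step)
    return geometry.propagate(seed, helix_step, 12)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_screw(rng, max_angle=170.0, max_rise=5.0):
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    point = rng.normal(scale=5.0, size=3)
    point -= (point @ axis) * axis  # canonical: perpendicular to the axis
    return geometry.ScrewTransform(
        rotation_angle=float(rng.uniform(5.0, max_angle)),
        axis=axis,
        axis_point=point,
        rise=float(rng.uniform(-max_rise, max_rise)),
    )
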