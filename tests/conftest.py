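import numpy as np
import pytest

from cerebdev.core import (
    DENDRITE,
    PARALLEL_FIBER,
    SOMA,
    SPHERE,
    Scene,
    SimVolume,
)


@pytest.fixture
def scene():
    """Empty full-scale scene."""
    return Scene(seed=0)


@pytest.fixture
def small_volume():
    return SimVolume((-20, -20, -20), (80, 70, 140),
                     (-20, -90, -20), (80, 140, 140))


def make_soma(scene, pos, radius=5.0, neuron_id=0):
    p = np.asarray(pos, dtype=float)
    return scene.add_front(neuron_id, p, p, radius, SOMA,
                           shape=SPHERE, active=True)


def scatter_fronts(scene, n, rng, tag=DENDRITE, radius=0.5, length=5.0,
                   lo=(0, 0, 0), hi=(100, 100, 100), neuron_base=100):
    """Drop n random cylinders into the scene without collision checking."""
    ids = []
    lo = np.asarray(lo, dtype=float)
    hi = np.asarray(hi, dtype=float)
    for i in range(n):
        a = rng.uniform(lo, hi)
        d = rng.normal(size=3)
        d = d / np.linalg.norm(d) * length
        ids.append(scene.add_front(neuron_base + i, a, a + d, radius, tag))
    return ids


def make_pf(scene, y0, y1, x, z, radius=0.5, neuron_id=500):
    return scene.add_front(neuron_id, (x, y0, z), (x, y1, z), radius,
                           PARALLEL_FIBER)
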