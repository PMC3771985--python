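import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True,
                          deadline=None)
settings.load_profile("deterministic")

from cryptabm.cell_cycle import reference_packing_radius
from cryptabm.geometry import CryptGeometry
from cryptabm.state import (CLASS_TA, PHASE_A, PHASE_G0, PHASE_S,
                            CryptState)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def geometry():
    """Full-size crypt sheet with birth-radius packing (width 22 x 9.5)."""
    return CryptGeometry()


@pytest.fixture
def tuned_geometry():
    """Full-size sheet fine-tuned with the population-average radius."""
    return CryptGeometry(packing_radius=reference_packing_radius())


@pytest.fixture
def small_geometry():
    return CryptGeometry(n_circumference=6, n_length=8)


def make_state(x, y, r=5.0, phase=PHASE_A, cell_class=CLASS_TA):
    """Scripted cell population at explicit positions."""
    x = np.asarray(x, dtype=float)
    n = x.size
    s = CryptState.empty(n)
    s.x[:] = x
    s.y[:] = np.asarray(y, dtype=float)
    s.r[:] = np.broadcast_to(np.asarray(r, dtype=float), (n,))
    s.phase[:] = np.broadcast_to(np.asarray(phase), (n,))
    s.cell_class[:] = np.broadcast_to(np.asarray(cell_class), (n,))
    return s


def random_state(rng, geometry, n=50, mature_fraction=0.5):
    """Random snapshot of n cells inside the crypt, mixed mature/cycling."""
    s = make_state(rng.uniform(0, geometry.width, n),
                   rng.uniform(0, geometry.height, n),
                   r=rng.uniform(4.0, 7.5, n))
    mature = rng.random(n) < mature_fraction
    s.phase[mature] = PHASE_G0
    s.phase[~mature] = rng.choice([PHASE_A, PHASE_S], size=(~mature).sum())
    return s


@pytest.fixture
def scripted_state():
    return make_state


@pytest.fixture
def random_snapshot():
    return random_state
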