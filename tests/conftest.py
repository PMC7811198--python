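import logging

import numpy as np
import pytest

import zconstrict as zc

logging.getLogger("zconstrict").setLevel(logging.ERROR)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def mini_membrane():
    return zc.fixtures.make_fixture("mini_membrane", seed=0)


@pytest.fixture()
def mini_ring():
    return zc.fixtures.make_fixture("mini_ring", seed=0)


@pytest.fixture()
def two_filaments():
    return zc.fixtures.make_fixture("two_filaments", seed=0)


@pytest.fixture()
def mini_wall():
    return zc.fixtures.make_fixture("mini_wall", seed=0)


def central_difference_check(system, force_fn, energy_fn, beads,
                             h=1e-6, tol=1e-5):
    """Relative max deviation between forces and -grad(energy)."""
    system.zero_forces()
    force_fn()
    F = system.forces[beads].copy()
    G = np.zeros_like(F)
    for r, b in enumerate(beads):
        for k in range(3):
            orig = system.positions[b, k]
            system.positions[b, k] = orig + h
            ep = energy_fn()
            system.positions[b, k] = orig - h
            em = energy_fn()
            system.positions[b, k] = orig
            G[r, k] = -(ep - em) / (2 * h)
    scale = max(np.abs(F).max(), np.abs(G).max(), 1e-8)
    return np.abs(F - G).max() / scale
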