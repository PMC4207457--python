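import numpy as np
import pytest

import chromoloop as cl


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20140)


@pytest.fixture()
def small_params():
    """A small confined ring with one loop, for force/dynamics checks."""
    return cl.SimulationParameters(
        n_monomers=60, volume_density=0.05, loops=[(20, 40)]
    )


@pytest.fixture(scope="session")
def random_ring_conformation():
    """An irregular but bounded closed-ring conformation (N=40)."""
    gen = np.random.default_rng(7)
    n = 40
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    x = np.c_[4 * np.cos(t), 4 * np.sin(t), 0.4 * gen.standard_normal(n)]
    x += 0.15 * gen.standard_normal((n, 3))
    return cl.Conformation(x)


def trefoil_coords(n_points: int = 120) -> np.ndarray:
    t = np.linspace(0, 2 * np.pi, n_points, endpoint=False)
    return np.c_[
        (2 + np.cos(3 * t)) * np.cos(2 * t),
        (2 + np.cos(3 * t)) * np.sin(2 * t),
        np.sin(3 * t),
    ]


def figure_eight_coords(n_points: int = 120) -> np.ndarray:
    t = np.linspace(0, 2 * np.pi, n_points, endpoint=False)
    return np.c_[
        (2 + np.cos(2 * t)) * np.cos(3 * t),
        (2 + np.cos(2 * t)) * np.sin(3 * t),
        np.sin(4 * t),
    ]
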