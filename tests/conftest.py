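import numpy as np
import pytest

from glefric import MemoryKernel, make_potential, simulate_gle


@pytest.fixture(scope="session")
def triple_well():
    """Butane-like dihedral profile: trans at 0, gauche at +-120 deg,
    trans->gauche barrier 3.5 k_BT, gauche offset 0.7 k_BT."""
    return make_potential("cosine_dihedral", barrier=3.5, gauche_offset=0.7)


@pytest.fixture(scope="session")
def harmonic_profile():
    return make_potential("harmonic", k=2.0)


@pytest.fixture(scope="session")
def quartic_profile():
    return make_potential("double_well_quartic", barrier=4.0, half_separation=1.0)


@pytest.fixture(scope="session")
def harmonic_gle_traj(harmonic_profile):
    """Well-resolved single-exponential GLE run in a harmonic well."""
    kernel = MemoryKernel.single_exponential(20.0, 0.5)
    return simulate_gle(
        harmonic_profile, kernel, mass=2.0, dt=0.01, n_steps=4_000_000, seed=1
    )


def block_stderr(x, n_blocks=20):
    """Standard error of the mean from contiguous block averages."""
    x = np.asarray(x)
    edges = np.linspace(0, x.size, n_blocks + 1).astype(int)
    means = np.array([x[a:b].mean() for a, b in zip(edges[:-1], edges[1:])])
    return means.std(ddof=1) / np.sqrt(n_blocks)
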