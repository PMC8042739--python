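import numpy as np
import pytest

from pavkit import simulate as sim


@pytest.fixture(scope="session")
def sim_output():
    """One full synthetic data set shared across tests (seed fixed)."""
    return sim.generate(sim.SimConfig(seed=1))


@pytest.fixture(scope="session")
def worked():
    return sim.make_worked_fixtures()


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def neutral_matrix(rng, n_sites, n_samples):
    """Sites x samples matrix with 1/k-shaped derived counts (no missing)."""
    ks = np.arange(1, n_samples)
    w = 1.0 / ks
    mat = np.zeros((n_sites, n_samples), dtype=np.int8)
    for i in range(n_sites):
        k = rng.choice(ks, p=w / w.sum())
        carriers = rng.choice(n_samples, size=k, replace=False)
        mat[i, carriers] = 1
    return mat


def balanced_matrix(rng, n_sites, n_samples, kappa=20.0):
    """Sites x samples matrix with Beta(kappa, kappa) intermediate frequencies."""
    mat = np.zeros((n_sites, n_samples), dtype=np.int8)
    for i in range(n_sites):
        f = rng.beta(kappa, kappa)
        mat[i] = rng.random(n_samples) < f
    return mat
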