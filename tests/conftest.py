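import dataclasses

import numpy as np
import pytest

import netctrl as nc

SMALL_SIZES = {"CON": 5, "DMN": 5, "VIS": 5, "SUB": 5}


def stable_random_matrix(n: int, seed: int, margin: float = 0.3,
                         density: float = 1.0) -> np.ndarray:
    rng = np.random.default_rng(seed)
    A = rng.normal(scale=0.5, size=(n, n))
    if density < 1.0:
        mask = rng.random((n, n)) < density
        np.fill_diagonal(mask, True)
        A = A * mask
    A[np.diag_indices(n)] = -np.abs(A[np.diag_indices(n)]) - 0.5
    return nc.ensure_stable(A, margin)


def make_ec(A: np.ndarray, **kw) -> nc.EffectiveConnectome:
    n = A.shape[0]
    return nc.EffectiveConnectome(A=A, nodes=nc.make_node_table({"SUB": n}), **kw)


@pytest.fixture
def scalar_ec():
    return make_ec(np.array([[-0.5]]))


@pytest.fixture
def chain_ec():
    # node 1 driven by node 0 with weight 2
    return make_ec(np.array([[-1.0, 0.0], [2.0, -1.0]]))


@pytest.fixture
def jordan_ec():
    return make_ec(np.array([[-1.0, 0.0], [1.0, -1.0]]))


@pytest.fixture(scope="session")
def small_cohort():
    cfg = nc.GeneratorConfig(n_nodes=20, rsn_sizes=SMALL_SIZES, density=0.5,
                             n_subjects=3, seed=11, stability_margin=0.1)
    return nc.generate_cohort(cfg)


@pytest.fixture(scope="session")
def big_cohort():
    """20 subjects x 74 nodes at the calibrated defaults (shared across the
    directional / acceptance tests)."""
    cfg = nc.GeneratorConfig(n_subjects=20, seed=7)
    return nc.generate_cohort(cfg)


@pytest.fixture(scope="session")
def big_cohort_energies(big_cohort):
    return [nc.pairwise_energies(ec) for ec in big_cohort]
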