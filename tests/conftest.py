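"""Shared fixtures: small seeded synthetic datasets, built once per session."""

import numpy as np
import pytest

from symflux.symcluster import SymClusterParams
from symflux.synthetic import gen_docking_ensemble


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_ensemble():
    """Two planted clusters (8, 12) plus 4 singletons, mild noise."""
    models, truth = gen_docking_ensemble(
        cluster_sizes=(8, 12), n_noise=4, noise_sigma=1.0, flip_prob=0.5, seed=101
    )
    return models, truth


@pytest.fixture(scope="session")
def small_params():
    return SymClusterParams(min_cluster_floor=3, min_cluster_frac=0.05)


@pytest.fixture(scope="session")
def clean_ensemble():
    """Noise-free, unjittered ensemble: members are exact symmetry/flip images."""
    models, truth = gen_docking_ensemble(
        cluster_sizes=(4, 4), n_noise=2, noise_sigma=0.0, flip_prob=0.5,
        seed=7, jitter_rigid=False,
    )
    return models, truth
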