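"""Shared fixtures: small graphs and cohorts used across test modules."""

import numpy as np
import pytest

from fatiguenet.network import ConnectionMatrix


def make_matrix(weights, names=None, **kw) -> ConnectionMatrix:
    weights = np.asarray(weights, dtype=float)
    if names is None:
        names = [f"n{i}" for i in range(weights.shape[0])]
    return ConnectionMatrix(tuple(names), weights, **kw)


def star_matrix(k: int = 12, weight: float = 1.0) -> ConnectionMatrix:
    """Hub node n0 linked to every leaf; leaves mutually unlinked."""
    w = np.zeros((k, k))
    w[0, 1:] = w[1:, 0] = weight
    return make_matrix(w)


def path_matrix(k: int = 3, weight: float = 1.0) -> ConnectionMatrix:
    w = np.zeros((k, k))
    for i in range(k - 1):
        w[i, i + 1] = w[i + 1, i] = weight
    return make_matrix(w)


def complete_matrix(k: int, weight: float = 1.0) -> ConnectionMatrix:
    w = np.full((k, k), weight)
    np.fill_diagonal(w, 0.0)
    return make_matrix(w)


def random_matrix(rng: np.random.Generator, k: int, p: float = 0.4) -> ConnectionMatrix:
    """Erdos-Renyi topology with uniform weights in (0, 1]."""
    upper = np.triu((rng.random((k, k)) < p).astype(float), k=1)
    vals = np.triu(rng.uniform(0.05, 1.0, (k, k)), k=1)
    w = upper * vals
    w = w + w.T
    return make_matrix(w)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def default_cohort():
    """One deterministic 9-participant, 4-intensity synthetic cohort."""
    from fatiguenet.synthetic import GeneratorConfig, generate_cohort

    return generate_cohort(GeneratorConfig(seed=42))
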