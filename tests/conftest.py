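import numpy as np
import pytest

import qrmeth


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_dataset():
    """Small synthetic dataset shared by pipeline-level tests."""
    spec = qrmeth.SyntheticSpec(
        n_cgis=40,
        n_samples=12,
        n_pos_controls=3,
        n_neg_controls=8,
        seed=11,
    )
    return qrmeth.simulate_dataset(spec)


@pytest.fixture(scope="session")
def small_call(small_dataset):
    """Score tables of the small dataset at tau = 0.85."""
    inference = qrmeth.InferenceSettings(n_boot=80, seed=5)
    score_tables, results, report = qrmeth.call_dataset(
        small_dataset.annotation,
        small_dataset.matrix,
        [0.85],
        [0.01, 0.02, 0.03, 0.04, 0.05],
        inference,
    )
    return score_tables, results, report


def structured_design(n_samples, n_probes, rng, affinity_sd=0.5, noise_sd=0.4):
    """Balanced two-way layout + matching dense design matrix."""
    si = np.repeat(np.arange(n_samples), n_probes)
    pi = np.tile(np.arange(n_probes), n_samples)
    n = n_samples * n_probes
    y = rng.normal(0.0, noise_sd, size=n) + rng.normal(0.0, affinity_sd, size=n_probes)[pi]
    k = n_samples + max(n_probes - 1, 0)
    X = np.zeros((n, k))
    X[np.arange(n), si] = 1.0
    if n_probes > 1:
        C = np.vstack([np.eye(n_probes - 1), -np.ones(n_probes - 1)])
        X[:, n_samples:] = C[pi]
    return si, pi, y, X
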