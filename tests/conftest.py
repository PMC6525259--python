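import numpy as np
import pytest

import linsimplex as ls


@pytest.fixture(scope="session")
def small_mixture():
    """Noiseless 3-type mixture, small enough for fast unit tests."""
    expr, truth = ls.simulate_dataset(
        n_genes=2_000, m_samples=30, k_types=3, noise_sd=0.0, seed=1
    )
    return expr, truth


@pytest.fixture(scope="session")
def small_norm(small_mixture):
    expr, _ = small_mixture
    return ls.row_normalize(expr)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def normalized_truth_corners(truth):
    """Row-normalized proportion rows: the true simplex corners in sample
    space."""
    H = truth.H
    return H / H.sum(axis=1, keepdims=True)
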