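import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from groupsil import ExpressionMatrix, GroupLabels  # noqa: E402
from groupsil.iolib import MODE_CONTINUOUS, MODE_COUNTS  # noqa: E402


@pytest.fixture
def rng():
    return np.random.default_rng(20180301)


@pytest.fixture
def small_counts():
    """3 genes x 2 samples integer matrix."""
    return ExpressionMatrix(
        ["g1", "g2", "g3"], ["A1", "B1"],
        np.array([[0.0, 2.0], [1.0, 0.0], [2.0, 3.0]]), MODE_COUNTS,
    )


@pytest.fixture
def two_group_labels():
    return GroupLabels({"A1": "A", "A2": "A", "A3": "A", "B1": "B", "B2": "B", "B3": "B"})


def random_counts(rng, n_genes=30, n_samples=6, zero_frac=0.3):
    vals = rng.poisson(8.0, size=(n_genes, n_samples)).astype(float)
    mask = rng.random((n_genes, n_samples)) < zero_frac
    vals[mask] = 0.0
    genes = [f"g{i}" for i in range(n_genes)]
    samples = [f"s{j}" for j in range(n_samples)]
    return ExpressionMatrix(genes, samples, vals, MODE_COUNTS)


def random_distance_matrix(rng, n):
    """A valid dissimilarity in [0, 2] from random points (rank-correlation-like)."""
    pts = rng.normal(size=(n, 5))
    d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    d = 2.0 * d / max(d.max(), 1e-9)
    np.fill_diagonal(d, 0.0)
    from groupsil import DistanceMatrix

    return DistanceMatrix([f"s{i}" for i in range(n)], d)
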