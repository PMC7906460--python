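import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

from mapalign.diffusion import (
    DiffusionBasis,
    DistanceMatrix,
    gknn_kernel,
    normalize_to_markov,
    spectral_decompose,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def point_cloud_distances(rng, n, dim=2):
    """Euclidean distance matrix of a uniform random point cloud."""
    pts = rng.random((n, dim))
    return DistanceMatrix(squareform(pdist(pts)))


def basis_from_cloud(rng, n, k_nn=7, drop_trivial=True):
    """Full diffusion basis of a random point cloud."""
    D = point_cloud_distances(rng, n)
    M = normalize_to_markov(gknn_kernel(D, k_nn))
    return spectral_decompose(M, drop_trivial=drop_trivial)


def orthonormal_basis(rng, n, m, eigenvalues=None):
    """DiffusionBasis with random orthonormal columns and given eigenvalues."""
    Q, _ = np.linalg.qr(rng.standard_normal((n, m)))
    if eigenvalues is None:
        eigenvalues = np.linspace(0.95, 0.5, m)
    return DiffusionBasis(eigenvalues=np.asarray(eigenvalues, float), eigenvectors=Q)
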