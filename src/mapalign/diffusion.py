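"""Diffusion maps from pairwise distance matrices.

The pipeline here follows the classic anisotropic (``alpha = 1``)
normalization of a Gaussian affinity kernel into a row-stochastic Markov
(heat) operator, whose spectral decomposition yields the diffusion map:
an embedding of the agents in which Euclidean distance equals diffusion
distance — the L2 difference between t-step random-walk distributions.

The affinity kernel is the self-tuning *Gaussian k-nearest-neighbor*
(GkNN) kernel

    K(x, y) = exp(-d(x, y)^2 / (d(x, k(x)) * d(y, k(y))))

where ``d(x, k(x))`` is the distance from ``x`` to its ``k``-th nearest
neighbor (the point itself excluded).  Its bandwidth adapts to the local
sampling density, and it is scale-free: rescaling all distances by a
constant leaves ``K`` unchanged.

The eigensolve is done on the symmetric conjugate of the Markov operator,
which guarantees a real spectrum and a Euclidean-orthonormal eigenbasis —
the geometry assumed by the analytic null of the alignment statistics in
:mod:`mapalign.alignment`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DistanceMatrix",
    "AffinityMatrix",
    "MarkovOperator",
    "DiffusionBasis",
    "DisconnectedGraphWarning",
    "gknn_kernel",
    "normalize_to_markov",
    "spectral_decompose",
    "diffusion_map",
    "diffusion_distance",
    "markov_power_from_basis",
]

_SYM_ATOL = 1e-8


class DisconnectedGraphWarning(UserWarning):
    """Raised when the affinity graph has more than one connected component."""


def _as_ids(agent_ids, n: int) -> tuple[str, ...]:
    if agent_ids is None:
        return tuple(str(i) for i in range(n))
    ids = tuple(str(a) for a in agent_ids)
    if len(ids) != n:
        raise ValueError(f"expected {n} agent ids, got {len(ids)}")
    return ids


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric nonnegative pairwise distances for one frame under one metric.

    Parameters
    ----------
    values
        ``(n, n)`` array; symmetrized and diagonal-zeroed on construction.
    agent_ids
        Ordered identifiers; defaults to ``"0" .. "n-1"``.
    """

    values: np.ndarray
    agent_ids: tuple[str, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError(f"distance matrix must be square, got shape {v.shape}")
        if v.shape[0] < 2:
            raise ValueError("need at least 2 agents")
        if not np.all(np.isfinite(v)):
            raise ValueError("distance matrix contains non-finite entries")
        if np.max(np.abs(v - v.T)) > _SYM_ATOL * (1.0 + np.max(np.abs(v))):
            raise ValueError("distance matrix is not symmetric")
        if np.min(v) < -_SYM_ATOL:
            raise ValueError("distance matrix has negative entries")
        v = 0.5 * (v + v.T)
        np.fill_diagonal(v, 0.0)
        np.clip(v, 0.0, None, out=v)
        v.flags.writeable = False
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "agent_ids", _as_ids(self.agent_ids, v.shape[0]))

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class AffinityMatrix:
    """Symmetric unit-diagonal kernel matrix with entries in [0, 1].

    Entries are mathematically in (0, 1] for the GkNN kernel; exact zeros can
    appear through floating-point underflow of very distant pairs.
    """

    values: np.ndarray
    agent_ids: tuple[str, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] < 2:
            raise ValueError(f"affinity matrix must be square with n >= 2, got {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ValueError("affinity matrix contains non-finite entries")
        if np.max(np.abs(v - v.T)) > _SYM_ATOL:
            raise ValueError("affinity matrix is not symmetric")
        if np.min(v) < 0 or np.max(v) > 1 + _SYM_ATOL:
            raise ValueError("affinity entries must lie in [0, 1]")
        if np.max(np.abs(np.diag(v) - 1.0)) > _SYM_ATOL:
            raise ValueError("affinity diagonal must be exactly 1")
        v = 0.5 * (v + v.T)
        np.fill_diagonal(v, 1.0)
        v.flags.writeable = False
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "agent_ids", _as_ids(self.agent_ids, v.shape[0]))

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class MarkovOperator:
    """Row-stochastic heat operator plus its symmetric conjugate.

    ``values`` is the Markov matrix A-hat; ``symmetric_conjugate`` is
    ``S = D^{1/2} A-hat D^{-1/2}`` with ``D = diag(stationary_weights)``,
    sharing A-hat's spectrum but symmetric, so its eigenvectors are
    Euclidean-orthonormal.
    """

    values: np.ndarray
    symmetric_conjugate: np.ndarray
    stationary_weights: np.ndarray
    agent_ids: tuple[str, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        rows = v.sum(axis=1)
        if np.max(np.abs(rows - 1.0)) > 1e-10:
            raise ValueError("rows of the Markov operator must sum to 1 within 1e-10")
        if np.min(v) < -1e-12:
            raise ValueError("Markov operator has negative entries")
        object.__setattr__(self, "agent_ids", _as_ids(self.agent_ids, v.shape[0]))

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class DiffusionBasis:
    """Sorted eigenpairs of the heat operator and the diffusion coordinates.

    ``eigenvectors`` columns are unit-norm and pairwise orthonormal when the
    basis comes from the symmetric-conjugate solve (the default).  With the
    trivial eigenpair removed (default), column ``j`` is the ``(j+1)``-th
    nontrivial mode, i.e. phi_1 is ``eigenvectors[:, 0]``.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    t: float = 1.0
    stationary_weights: np.ndarray | None = None
    trivial_removed: bool = True
    disconnected: bool = False
    orthonormal: bool = True
    agent_ids: tuple[str, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        lam = np.asarray(self.eigenvalues, dtype=float)
        phi = np.asarray(self.eigenvectors, dtype=float)
        if phi.ndim != 2 or phi.shape[1] != lam.shape[0]:
            raise ValueError("eigenvector matrix shape does not match eigenvalues")
        if np.any(np.diff(lam) > 1e-10):
            raise ValueError("eigenvalues must be non-increasing")
        object.__setattr__(self, "eigenvalues", lam)
        object.__setattr__(self, "eigenvectors", phi)
        object.__setattr__(self, "agent_ids", _as_ids(self.agent_ids, phi.shape[0]))

    @property
    def n(self) -> int:
        return self.eigenvectors.shape[0]

    @property
    def size(self) -> int:
        """Number of retained eigenpairs."""
        return self.eigenvalues.shape[0]

    @property
    def coords(self) -> np.ndarray:
        """Diffusion coordinates psi_k = lambda_k^t phi_k, all modes."""
        return diffusion_map(self, self.size)


def gknn_kernel(
    D: DistanceMatrix,
    k_nn: int = 7,
    *,
    distance_floor: bool = False,
) -> AffinityMatrix:
    """Self-tuning Gaussian k-nearest-neighbor affinity kernel.

    The bandwidth for the pair ``(i, j)`` is the product of each point's
    distance to its ``k_nn``-th nearest neighbor (self excluded), making the
    kernel adapt to local density and invariant to a global rescaling of the
    distances.

    Parameters
    ----------
    D
        Pairwise distances for one frame.
    k_nn
        Nearest-neighbor index used for the local bandwidth; must satisfy
        ``1 <= k_nn < n``.
    distance_floor
        If True, duplicate points (zero k-NN distance) are tolerated by
        flooring bandwidths at ``1e-12 * median(D)`` instead of raising.
    """
    n = D.n
    if not 1 <= k_nn < n:
        raise ValueError(f"k_nn must satisfy 1 <= k_nn < n = {n}, got {k_nn}")
    vals = D.values
    offdiag = vals + np.diag(np.full(n, np.inf))
    # k_nn-th nearest neighbor excluding self: column k_nn - 1 of the sorted rows
    h = np.sort(offdiag, axis=1)[:, k_nn - 1]
    if np.any(h <= 0.0):
        if distance_floor:
            floor = 1e-12 * float(np.median(vals[~np.eye(n, dtype=bool)]))
            if floor <= 0.0:
                raise ValueError("all pairwise distances are zero; cannot build kernel")
            h = np.maximum(h, floor)
        else:
            i = int(np.argmax(h <= 0.0))
            dup = np.flatnonzero((vals[i] == 0.0) & (np.arange(n) != i))
            j = int(dup[0]) if dup.size else i
            raise ValueError(
                f"duplicate points: agents {D.agent_ids[i]!r} and {D.agent_ids[j]!r} "
                f"give a zero {k_nn}-NN bandwidth; enable distance_floor to tolerate"
            )
    K = np.exp(-(vals**2) / np.outer(h, h))
    np.fill_diagonal(K, 1.0)
    return AffinityMatrix(K, agent_ids=D.agent_ids)


def normalize_to_markov(A: AffinityMatrix) -> MarkovOperator:
    """Anisotropic (alpha = 1) normalization of an affinity into a Markov operator.

    First divides out the sampling density from both sides,
    ``A'_{ij} = A_{ij} / (sigma_i sigma_j)`` with ``sigma`` the row sums of
    ``A``, then row-normalizes ``A'`` into the row-stochastic heat operator.
    """
    sig = A.values.sum(axis=1)
    if np.any(sig <= 0.0):
        raise ValueError("affinity matrix has a nonpositive row sum")
    A1 = A.values / np.outer(sig, sig)
    d = A1.sum(axis=1)
    if np.any(d <= 0.0):
        raise ValueError("density-normalized affinity has a nonpositive row sum")
    markov = A1 / d[:, None]
    conj = A1 / np.sqrt(np.outer(d, d))
    return MarkovOperator(
        values=markov,
        symmetric_conjugate=conj,
        stationary_weights=d,
        agent_ids=A.agent_ids,
    )


def _fix_signs(phi: np.ndarray) -> np.ndarray:
    """Make the largest-magnitude entry of each column positive (ties: first)."""
    idx = np.argmax(np.abs(phi), axis=0)
    signs = np.sign(phi[idx, np.arange(phi.shape[1])])
    signs[signs == 0] = 1.0
    return phi * signs


def spectral_decompose(
    M: MarkovOperator,
    drop_trivial: bool = True,
    *,
    t: float = 1.0,
    orthonormal: bool = True,
) -> DiffusionBasis:
    """Eigendecompose the heat operator via its symmetric conjugate.

    Eigenpairs are sorted by descending eigenvalue.  The trivial pair
    (eigenvalue ~1, geometry-free stationary mode) is removed by default so
    that mode 1 is the first informative diffusion coordinate.  If more than
    one eigenvalue sits within 1e-10 of 1 the affinity graph is disconnected;
    a :class:`DisconnectedGraphWarning` is emitted and the basis flagged.

    With ``orthonormal=False`` the right-eigenvectors of the Markov operator
    itself (unit-normalized, generally non-orthogonal) are returned instead.
    """
    evals, evecs = np.linalg.eigh(M.symmetric_conjugate)
    order = np.argsort(-evals, kind="stable")
    evals = evals[order]
    evecs = evecs[:, order]

    disconnected = int(np.sum(evals > 1.0 - 1e-10)) > 1
    if disconnected:
        warnings.warn(
            "affinity graph appears disconnected: multiple eigenvalues within "
            "1e-10 of 1; diffusion coordinates mix component indicators",
            DisconnectedGraphWarning,
            stacklevel=2,
        )
    evals = np.clip(evals, -1.0, 1.0)

    if drop_trivial:
        evals = evals[1:]
        evecs = evecs[:, 1:]

    if not orthonormal:
        evecs = evecs / np.sqrt(M.stationary_weights)[:, None]
        evecs = evecs / np.linalg.norm(evecs, axis=0)

    evecs = _fix_signs(np.ascontiguousarray(evecs))
    return DiffusionBasis(
        eigenvalues=evals,
        eigenvectors=evecs,
        t=t,
        stationary_weights=np.asarray(M.stationary_weights, dtype=float),
        trivial_removed=drop_trivial,
        disconnected=disconnected,
        orthonormal=orthonormal,
        agent_ids=M.agent_ids,
    )


def diffusion_map(B: DiffusionBasis, k: int) -> np.ndarray:
    """First ``k`` diffusion coordinates: column ``j`` is ``lambda_j^t phi_j``.

    Truncating to the leading ``k`` coordinates gives the optimal
    ``k``-dimensional embedding of the diffusion geometry.
    """
    if not 1 <= k <= B.size:
        raise ValueError(f"k must satisfy 1 <= k <= {B.size}, got {k}")
    lam = B.eigenvalues[:k]
    scale = np.sign(lam) * np.abs(lam) ** B.t if B.t != 1.0 else lam
    return B.eigenvectors[:, :k] * scale


def diffusion_distance(M: MarkovOperator, t: int, i: int, j: int) -> float:
    """L2 distance between the t-step transition distributions from i and j.

    Computed by direct matrix power; serves as the oracle for the
    embedding-based distance.
    """
    n = M.n
    for idx in (i, j):
        if not 0 <= idx < n:
            raise IndexError(f"agent index {idx} out of range for n = {n}")
    if t < 0:
        raise ValueError("t must be a nonnegative integer")
    At = np.linalg.matrix_power(M.values, t)
    return float(np.linalg.norm(At[i] - At[j]))


def markov_power_from_basis(M: MarkovOperator, t: int) -> np.ndarray:
    """Reconstruct ``A-hat^t`` from the full spectral decomposition.

    Uses the bi-orthogonal expansion through the symmetric conjugate:
    ``A-hat^t = D^{-1/2} (Phi Lambda^t Phi^T) D^{1/2}``.
    """
    B = spectral_decompose(M, drop_trivial=False)
    d = np.asarray(M.stationary_weights, dtype=float)
    inner = (B.eigenvectors * B.eigenvalues**t) @ B.eigenvectors.T
    return (inner * np.sqrt(d)[None, :]) / np.sqrt(d)[:, None]
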