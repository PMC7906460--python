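"""Frame fingerprints and unsupervised macrostate classification.

A frame's macro-scale organization is fingerprinted by its *covariance
vector*: the inner products ``xi_{i,j} = <psi_i^{(1)}, psi_j^{(2)}>``
between the two truncated diffusion maps' coordinates, taken in absolute
value and sorted by decreasing magnitude.  Sorting removes the sign and
index ambiguity of eigenvectors (nearby operators can swap or flip modes),
leaving a stable k^2-dimensional signature that embeds every frame in a
shared space.

Frames whose map alignment falls below a Z threshold (default 3, i.e.
three null standard deviations) carry no detectable macro-scale relation
and are gated into the incoherent group ``N``; the remaining frames are
clustered by k-means, and clusters are named G1, G2, ... in order of
decreasing mean Z so that the naming reflects the relative level of
organization rather than arbitrary k-means label order.

The module also provides the classic polarization / rotation order
parameters used as the reference classification for fish schools.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from .diffusion import DiffusionBasis

__all__ = [
    "CovarianceVector",
    "StateLabeling",
    "OrderParameters",
    "covariance_matrix",
    "covariance_vector",
    "classify_frames",
    "order_parameters",
    "reference_state",
]


@dataclass(frozen=True)
class CovarianceVector:
    """Sorted-magnitude fingerprint of one frame's cross-map covariances."""

    frame: int
    k: int
    raw: np.ndarray
    sorted: np.ndarray

    @classmethod
    def from_matrix(cls, frame: int, xi: np.ndarray) -> "CovarianceVector":
        xi = np.asarray(xi, dtype=float)
        return cls(frame=frame, k=xi.shape[0], raw=xi, sorted=covariance_vector(xi))


@dataclass(frozen=True)
class StateLabeling:
    """Per-frame macrostate labels from gating + clustering.

    ``labels`` maps frame -> label in {"N", "G1", ..., "Gm"}; clusters are
    named by decreasing mean Z.  ``cluster_mean_z`` and ``centers`` are
    indexed by the final names.
    """

    labels: dict[int, str]
    z_threshold: float
    n_clusters: int
    seed: int
    cluster_mean_z: dict[str, float]
    centers: dict[str, np.ndarray]


@dataclass(frozen=True)
class OrderParameters:
    """Polarization / rotation order parameters of one frame."""

    frame: int
    o_p: float
    o_r: float
    centroid: np.ndarray
    state: str
    n_zero_speed: int = 0


def covariance_matrix(B1: DiffusionBasis, B2: DiffusionBasis, k: int) -> np.ndarray:
    """Cross-covariances of the two truncated diffusion maps.

    Entry ``(i, j)`` is ``<psi_i^{(1)}, psi_j^{(2)}> =
    lambda_i^{(1)} lambda_j^{(2)} <phi_i^{(1)}, phi_j^{(2)}>`` at t = 1.
    """
    if B1.n != B2.n:
        raise ValueError(f"bases have different agent counts: {B1.n} vs {B2.n}")
    if B1.agent_ids != B2.agent_ids:
        diff = set(B1.agent_ids) ^ set(B2.agent_ids)
        raise ValueError(
            "bases are not over the same ordered agent set; "
            f"symmetric difference: {sorted(diff) if diff else 'same set, different order'}"
        )
    if not 1 <= k <= min(B1.size, B2.size):
        raise ValueError(f"k must satisfy 1 <= k <= {min(B1.size, B2.size)}, got {k}")
    G = B1.eigenvectors[:, :k].T @ B2.eigenvectors[:, :k]
    return np.outer(B1.eigenvalues[:k], B2.eigenvalues[:k]) * G


def covariance_vector(xi: np.ndarray) -> np.ndarray:
    """Magnitudes of a covariance matrix sorted in decreasing order.

    Ties are broken by row-major original index, making the ordering map
    deterministic; the result is invariant to eigenvector sign flips.
    """
    xi = np.asarray(xi, dtype=float)
    if not np.all(np.isfinite(xi)):
        raise ValueError("covariance matrix has non-finite entries")
    flat = np.abs(xi).ravel(order="C")
    order = np.argsort(-flat, kind="stable")
    return flat[order]


def classify_frames(
    frames,
    z_threshold: float = 3.0,
    n_clusters: int = 3,
    seed: int = 0,
    n_restarts: int = 10,
) -> StateLabeling:
    """Gate incoherent frames and k-means-cluster the coherent fingerprints.

    Parameters
    ----------
    frames
        Iterable of ``(frame, z, vector)`` with ``vector`` the sorted
        covariance vector (all the same length).
    z_threshold
        Frames with ``z < z_threshold`` are labeled ``"N"`` (incoherent) and
        excluded from clustering.
    n_clusters, seed, n_restarts
        k-means settings; the best-inertia solution over ``n_restarts``
        seeded initializations is kept.
    """
    items = [(int(f), float(z), np.asarray(v, dtype=float)) for f, z, v in frames]
    if items:
        L = items[0][2].shape[0]
        if any(v.shape[0] != L for _, _, v in items):
            raise ValueError("all covariance vectors must have the same length")
    coherent = [(f, z, v) for f, z, v in items if z >= z_threshold]
    labels = {f: "N" for f, z, _ in items if z < z_threshold}

    if not coherent:
        return StateLabeling(
            labels=labels, z_threshold=z_threshold, n_clusters=n_clusters,
            seed=seed, cluster_mean_z={}, centers={},
        )
    if len(coherent) < n_clusters:
        raise ValueError(
            f"only {len(coherent)} coherent frames but {n_clusters} clusters requested"
        )
    X = np.stack([v for _, _, v in coherent])
    km = KMeans(n_clusters=n_clusters, n_init=n_restarts, random_state=seed)
    raw = km.fit_predict(X)

    zs = np.array([z for _, z, _ in coherent])
    mean_z = np.array([zs[raw == c].mean() for c in range(n_clusters)])
    order = np.argsort(-mean_z, kind="stable")  # G1 = most organized
    name_of = {int(c): f"G{rank + 1}" for rank, c in enumerate(order)}

    for (f, _, _), c in zip(coherent, raw):
        labels[f] = name_of[int(c)]
    return StateLabeling(
        labels=labels,
        z_threshold=z_threshold,
        n_clusters=n_clusters,
        seed=seed,
        cluster_mean_z={name_of[int(c)]: float(mean_z[c]) for c in range(n_clusters)},
        centers={name_of[int(c)]: km.cluster_centers_[c].copy() for c in range(n_clusters)},
    )


def order_parameters(
    positions: np.ndarray,
    velocities: np.ndarray,
    frame: int = 0,
) -> OrderParameters:
    """Polarization O_p and rotation O_r of one frame.

    ``O_p`` is the norm of the mean unit velocity; ``O_r`` the norm of the
    mean cross product (scalar z-component in 2-D) of unit radial vectors
    from the centroid with unit velocities.  Zero-speed agents contribute
    zero unit vectors (counted in ``n_zero_speed``); agents sitting at the
    centroid contribute zero to O_r.  All speeds zero raises.
    """
    p = np.asarray(positions, dtype=float)
    v = np.asarray(velocities, dtype=float)
    if p.ndim != 2 or p.shape[1] != 2 or p.shape != v.shape:
        raise ValueError("positions and velocities must both have shape (n, 2)")
    if p.shape[0] < 2:
        raise ValueError("need at least 2 agents")
    speeds = np.linalg.norm(v, axis=1)
    moving = speeds > 0
    if not np.any(moving):
        raise ValueError("all agent speeds are zero; order parameters undefined")
    n = p.shape[0]
    v_hat = np.zeros_like(v)
    v_hat[moving] = v[moving] / speeds[moving, None]

    c = p.mean(axis=0)
    q = p - c
    q_norm = np.linalg.norm(q, axis=1)
    off = q_norm > 0
    q_hat = np.zeros_like(q)
    q_hat[off] = q[off] / q_norm[off, None]

    o_p = float(np.linalg.norm(v_hat.sum(axis=0)) / n)
    cross = q_hat[:, 0] * v_hat[:, 1] - q_hat[:, 1] * v_hat[:, 0]
    o_r = float(abs(cross.sum()) / n)
    o_p, o_r = min(o_p, 1.0), min(o_r, 1.0)
    return OrderParameters(
        frame=frame, o_p=o_p, o_r=o_r, centroid=c,
        state=reference_state(o_p, o_r),
        n_zero_speed=int(np.sum(~moving)),
    )


def reference_state(o_p: float, o_r: float) -> str:
    """Demarcate milling / swarming / polarized / transitional states.

    Milling: O_p <= 0.35 and O_r >= 0.65; swarming: both <= 0.35;
    polarized: O_p >= 0.65 and O_r <= 0.35; anything else transitional.
    """
    for name, val in (("o_p", o_p), ("o_r", o_r)):
        if not 0.0 <= val <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {val}")
    if o_p <= 0.35 and o_r >= 0.65:
        return "milling"
    if o_p <= 0.35 and o_r <= 0.35:
        return "swarming"
    if o_p >= 0.65 and o_r <= 0.35:
        return "polarized"
    return "transitional"
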