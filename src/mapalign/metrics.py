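"""Per-frame distance matrices from agent trajectories.

Two metrics are provided, matching the two "lenses" the alignment analysis
compares:

* ``d1`` — instantaneous spatial proximity (Euclidean, planar or toroidal);
* ``d2`` — a kernel-smoothed L2 distance between two agents' recent velocity
  profiles, optionally minimized over a relative time lag so that a follower
  whose trajectory repeats a leader's with delay still registers as close.

The profile kernel is an exponential-decay weight ``kappa_s ~ exp(-s / tau)``
over the ``w`` most recent frames, normalized to sum to one, so a constant
velocity offset ``u`` over the window yields distance ``|u|``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist, pdist, squareform

from .diffusion import DistanceMatrix

__all__ = [
    "MetricConfig",
    "TrajectoryWindow",
    "position_distance_matrix",
    "velocity_profile_distance_matrix",
    "lagged_velocity_distance_matrix",
]


@dataclass(frozen=True)
class MetricConfig:
    """Settings for the velocity-profile metric.

    Parameters
    ----------
    window
        Profile length ``w`` in frames (default 10).
    tau
        Exponential decay constant of the profile kernel, in frames.
    max_lag
        Largest relative time shift searched by the lagged metric, in frames.
        0 for simulation data; 60 (2 s at 30 fps) for fish-like data.
    geometry
        ``"planar"`` or ``"torus"`` (period ``period`` per axis).
    frame_rate
        Frames per second, recorded so lags can be expressed in seconds.
    """

    window: int = 10
    tau: float = 5.0
    max_lag: int = 0
    geometry: str = "planar"
    period: float = 1.0
    frame_rate: float = 30.0

    def __post_init__(self):
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if self.max_lag < 0:
            raise ValueError("max_lag must be >= 0")
        if self.tau <= 0:
            raise ValueError("tau must be > 0")
        if self.geometry not in ("planar", "torus"):
            raise ValueError(f"unknown geometry {self.geometry!r}")

    @property
    def history_depth(self) -> int:
        """Frames of history a window needs: ``window + max_lag``."""
        return self.window + self.max_lag

    def kernel_weights(self) -> np.ndarray:
        """Normalized decay weights kappa_s, s = 0 .. window-1."""
        k = np.exp(-np.arange(self.window) / self.tau)
        return k / k.sum()


@dataclass(frozen=True)
class TrajectoryWindow:
    """History of positions and velocities ending at one frame.

    ``positions[s]`` and ``velocities[s]`` are the ``(n, 2)`` arrays ``s``
    frames *before* ``frame`` (``s = 0`` is the frame itself).  All agents
    must be present for the full depth; agents with gaps are excluded
    upstream by the trajectory reader.
    """

    frame: int
    positions: np.ndarray
    velocities: np.ndarray
    agent_ids: tuple[str, ...] = field(default=None)  # type: ignore[assignment]
    geometry: str = "planar"
    period: float = 1.0
    frame_rate: float = 30.0

    def __post_init__(self):
        p = np.asarray(self.positions, dtype=float)
        v = np.asarray(self.velocities, dtype=float)
        if p.ndim != 3 or p.shape[2] != 2 or p.shape != v.shape:
            raise ValueError(
                "positions and velocities must both have shape (depth, n, 2); "
                f"got {p.shape} and {v.shape}"
            )
        if p.shape[0] < 1:
            raise ValueError("window depth must be >= 1")
        object.__setattr__(self, "positions", p)
        object.__setattr__(self, "velocities", v)
        ids = self.agent_ids
        if ids is None:
            ids = tuple(str(i) for i in range(p.shape[1]))
        else:
            ids = tuple(str(a) for a in ids)
            if len(ids) != p.shape[1]:
                raise ValueError("agent_ids length does not match n")
        object.__setattr__(self, "agent_ids", ids)

    @property
    def depth(self) -> int:
        return self.positions.shape[0]

    @property
    def n(self) -> int:
        return self.positions.shape[1]


def position_distance_matrix(
    positions: np.ndarray,
    geometry: str = "planar",
    period: float = 1.0,
    agent_ids=None,
) -> DistanceMatrix:
    """Pairwise Euclidean (planar) or geodesic (torus) distances at one frame."""
    p = np.asarray(positions, dtype=float)
    if p.ndim != 2 or p.shape[1] != 2:
        raise ValueError(f"positions must have shape (n, 2), got {p.shape}")
    if p.shape[0] < 2:
        raise ValueError("need at least 2 agents")
    bad = np.flatnonzero(~np.all(np.isfinite(p), axis=1))
    if bad.size:
        ids = agent_ids if agent_ids is not None else [str(i) for i in range(p.shape[0])]
        names = [str(ids[i]) for i in bad]
        raise ValueError(f"non-finite coordinates for agents: {names}")
    if geometry == "planar":
        vals = squareform(pdist(p))
    elif geometry == "torus":
        delta = np.abs(p[:, None, :] - p[None, :, :])
        delta = np.minimum(delta, period - delta)
        vals = np.sqrt(np.sum(delta**2, axis=-1))
    else:
        raise ValueError(f"unknown geometry {geometry!r}")
    return DistanceMatrix(vals, agent_ids=agent_ids)


def _weighted_profiles(velocities: np.ndarray, weights: np.ndarray, lag: int) -> np.ndarray:
    """Stack sqrt-weighted velocity windows shifted ``lag`` frames back.

    Returns an ``(n, 2w)`` array whose rows are the concatenated, weighted
    profile of each agent, so plain Euclidean distances between rows equal
    the kernel-smoothed profile distance.
    """
    w = weights.shape[0]
    seg = velocities[lag : lag + w]  # (w, n, 2), index s = frames back
    seg = seg * np.sqrt(weights)[:, None, None]
    return np.transpose(seg, (1, 0, 2)).reshape(seg.shape[1], 2 * w)


def velocity_profile_distance_matrix(W: TrajectoryWindow, cfg: MetricConfig) -> DistanceMatrix:
    """Kernel-smoothed L2 distance between recent velocity profiles (no lag).

    ``d(i, j)^2 = sum_s kappa_s |v_i(t-s) - v_j(t-s)|^2`` over
    ``s = 0 .. w-1``, with normalized exponential-decay weights.
    """
    if W.depth < cfg.window:
        raise ValueError(
            f"window of length {cfg.window} requested but only {W.depth} frames available"
        )
    U = _weighted_profiles(W.velocities, cfg.kernel_weights(), 0)
    vals = squareform(pdist(U))
    return DistanceMatrix(vals, agent_ids=W.agent_ids)


def lagged_velocity_distance_matrix(W: TrajectoryWindow, cfg: MetricConfig) -> DistanceMatrix:
    """Velocity-profile distance minimized over a relative time lag.

    For each pair the profile distance is evaluated with either agent's
    window starting up to ``max_lag`` frames earlier, and the minimum over
    all ``2 * max_lag + 1`` alignments is taken.  Minimizing over which agent
    is shifted makes the result symmetric by construction, and it can only
    decrease relative to the lag-0 distance.
    """
    depth_needed = cfg.window + cfg.max_lag
    if W.depth < depth_needed:
        raise ValueError(
            f"lagged metric needs {depth_needed} frames of history "
            f"(window {cfg.window} + max_lag {cfg.max_lag}); got {W.depth}"
        )
    weights = cfg.kernel_weights()
    U0 = _weighted_profiles(W.velocities, weights, 0)
    best = cdist(U0, U0, "sqeuclidean")
    for lag in range(1, cfg.max_lag + 1):
        Ul = _weighted_profiles(W.velocities, weights, lag)
        m = cdist(U0, Ul, "sqeuclidean")
        np.minimum(best, m, out=best)
        np.minimum(best, m.T, out=best)
    vals = np.sqrt(np.maximum(best, 0.0))
    np.fill_diagonal(vals, 0.0)
    return DistanceMatrix(vals, agent_ids=W.agent_ids)
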