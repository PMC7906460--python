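"""End-to-end orchestration: trajectories -> per-frame stats -> macrostates.

For each analyzable frame the pipeline builds both distance matrices
(spatial proximity and lagged velocity profile), turns each into a
diffusion basis, evaluates the map alignment statistic in both directions,
and fingerprints the frame with its covariance vector.  After the sweep,
frames below the Z gate are labeled incoherent (``N``) and the remainder
are clustered into macrostates.

Frames that fail a precondition (too few agents, insufficient history,
degenerate kernels) never abort a run: the error is recorded and the frame
skipped.  With fixed seeds the whole run is deterministic; outputs embed a
hash of the resolved configuration for provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import alignment, diffusion, macrostate, metrics
from .io import TrajectoryTable

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]

log = logging.getLogger("mapalign.pipeline")


@dataclass(frozen=True)
class PipelineConfig:
    """Resolved settings for one analysis run.

    ``flocking()`` (k = 10, no lag, toroidal geometry) and ``schooling()``
    (k = 15, 60-frame lag, planar) give the standard presets for the two
    study systems; ``z_threshold = 3`` and ``n_clusters = 3`` are the
    standard gate and cluster count.
    """

    window: int = 10
    tau: float = 5.0
    max_lag: int = 0
    geometry: str = "planar"
    period: float = 1.0
    frame_rate: float = 30.0
    k_nn: int = 7
    k: int = 10
    t: float = 1.0
    z_threshold: float = 3.0
    n_clusters: int = 3
    seed: int = 0
    stride: int = 1
    min_n: int = 30
    distance_floor: bool = True
    n_restarts: int = 10

    @classmethod
    def flocking(cls, **overrides) -> "PipelineConfig":
        return cls(**{**dict(k=10, max_lag=0, geometry="torus"), **overrides})

    @classmethod
    def schooling(cls, **overrides) -> "PipelineConfig":
        return cls(**{**dict(k=15, max_lag=60, geometry="planar"), **overrides})

    def metric_config(self) -> metrics.MetricConfig:
        return metrics.MetricConfig(
            window=self.window, tau=self.tau, max_lag=self.max_lag,
            geometry=self.geometry, period=self.period, frame_rate=self.frame_rate,
        )

    def hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass(frozen=True)
class PipelineResult:
    """Per-frame statistics, macrostate labeling, and skipped-frame log."""

    stats: pd.DataFrame
    labeling: macrostate.StateLabeling
    vectors: dict
    errors: tuple[tuple[int, str], ...]
    config: PipelineConfig
    config_hash: str

    def write_outputs(self, out_dir) -> None:
        """Write stats/labels/centers CSVs with a config-provenance header."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        header = [f"mapalign config_hash={self.config_hash}"] + [
            f"{k} = {v}" for k, v in sorted(dataclasses.asdict(self.config).items())
        ]
        for name, df in (
            ("stats.csv", self.stats),
            ("labels.csv", self.stats[["frame", "cluster"]]),
        ):
            with open(out / name, "w") as fh:
                for line in header:
                    fh.write(f"# {line}\n")
                df.to_csv(fh, index=False)
        if self.labeling.centers:
            centers = pd.DataFrame(
                {name: c for name, c in sorted(self.labeling.centers.items())}
            ).T
            with open(out / "centers.csv", "w") as fh:
                for line in header:
                    fh.write(f"# {line}\n")
                centers.to_csv(fh, header=False)


def _frame_stats(table: TrajectoryTable, frame: int, cfg: PipelineConfig, mcfg):
    depth = mcfg.history_depth
    W, dropped = table.window(frame, depth)
    n = W.n
    floor = max(cfg.min_n, cfg.k + 1, cfg.k_nn + 1)
    if n < floor:
        raise ValueError(f"n = {n} below required minimum {floor}")

    d1 = metrics.position_distance_matrix(
        W.positions[0], geometry=cfg.geometry, period=cfg.period, agent_ids=W.agent_ids
    )
    if cfg.max_lag > 0:
        d2 = metrics.lagged_velocity_distance_matrix(W, mcfg)
    else:
        d2 = metrics.velocity_profile_distance_matrix(W, mcfg)

    bases = []
    for dm in (d1, d2):
        A = diffusion.gknn_kernel(dm, k_nn=cfg.k_nn, distance_floor=cfg.distance_floor)
        M = diffusion.normalize_to_markov(A)
        bases.append(diffusion.spectral_decompose(M, t=cfg.t))
    b1, b2 = bases

    fwd = alignment.map_alignment_statistic(b1, b2, cfg.k)
    rev = alignment.map_alignment_statistic(b2, b1, cfg.k)
    xi = macrostate.covariance_matrix(b1, b2, cfg.k)
    vec = macrostate.covariance_vector(xi)
    op = macrostate.order_parameters(W.positions[0], W.velocities[0], frame=frame)
    row = dict(
        frame=frame, n=n, o_p=op.o_p, o_r=op.o_r, reference_state=op.state,
        z_forward=fwd.z, z_reverse=rev.z,
        unweightable=fwd.unweightable or rev.unweightable,
        n_dropped=len(dropped),
    )
    return row, vec


def run_pipeline(table: TrajectoryTable, config: PipelineConfig) -> PipelineResult:
    """Run the full analysis over every analyzable frame of a trajectory table.

    A frame is analyzable when at least ``min_n`` agents (and more than
    ``k`` and ``k_nn``) carry the full ``window + max_lag`` history.  The
    incoherence gate uses the forward statistic Z(position, velocity).
    Raises if no frame is analyzable, naming the limiting constraint.
    """
    mcfg = config.metric_config()
    depth = mcfg.history_depth
    frames = table.frames
    candidates = [int(f) for f in frames[::config.stride] if f - depth + 1 >= frames.min()]
    rows, vectors, errors = [], {}, []
    for f in candidates:
        try:
            row, vec = _frame_stats(table, f, config, mcfg)
        except (ValueError, KeyError) as exc:
            errors.append((f, str(exc)))
            continue
        rows.append(row)
        vectors[f] = vec
    if not rows:
        detail = errors[-1][1] if errors else f"no frame has {depth} frames of history"
        raise ValueError(f"zero analyzable frames ({len(errors)} skipped; last: {detail})")

    stats = pd.DataFrame(rows)
    gated = [(r["frame"], r["z_forward"], vectors[r["frame"]]) for r in rows]
    n_coherent = sum(1 for _, z, _ in gated if z >= config.z_threshold)
    if n_coherent >= config.n_clusters:
        labeling = macrostate.classify_frames(
            gated, z_threshold=config.z_threshold, n_clusters=config.n_clusters,
            seed=config.seed, n_restarts=config.n_restarts,
        )
    else:
        log.warning(
            "only %d coherent frames (< %d clusters); all coherent frames labeled G1",
            n_coherent, config.n_clusters,
        )
        labels = {
            int(f): ("N" if z < config.z_threshold else "G1") for f, z, _ in gated
        }
        labeling = macrostate.StateLabeling(
            labels=labels, z_threshold=config.z_threshold, n_clusters=config.n_clusters,
            seed=config.seed, cluster_mean_z={}, centers={},
        )
    stats["cluster"] = [labeling.labels[r["frame"]] for r in rows]
    log.info(
        "analyzed %d frames (%d skipped); %d gated incoherent",
        len(rows), len(errors), sum(1 for v in labeling.labels.values() if v == "N"),
    )
    return PipelineResult(
        stats=stats, labeling=labeling, vectors=vectors,
        errors=tuple(errors), config=config, config_hash=config.hash(),
    )
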