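"""Trajectory tables: the tidy CSV format and windowed access.

The canonical on-disk format is a tidy CSV with columns
``frame, agent_id, x, y`` and optional ``vx, vy`` (domain units per frame).
Frames need not contain the same agents; each agent's presence is indexed
as a set of contiguous runs, and analysis windows only use agents present
for the window's full depth — agents with gaps are dropped from that frame
and logged.

When velocity columns are absent they are synthesized per agent by central
finite differences over each contiguous presence run (forward/backward
differences at run ends), and the affected agents are recorded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .metrics import TrajectoryWindow

__all__ = ["TrajectoryTable", "read_trajectories", "write_trajectories"]

log = logging.getLogger("mapalign.io")

_REQUIRED = ("frame", "agent_id", "x", "y")


@dataclass
class TrajectoryTable:
    """Validated tidy trajectory table with per-agent presence runs."""

    df: pd.DataFrame
    synthesized_velocity_agents: tuple[str, ...] = ()
    runs: dict = field(default_factory=dict, repr=False)  # agent -> [(start, end)]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "TrajectoryTable":
        missing = [c for c in _REQUIRED if c not in df.columns]
        if missing:
            raise ValueError(f"trajectory table missing columns: {missing}")
        df = df.copy()
        df["frame"] = df["frame"].astype(int)
        df["agent_id"] = df["agent_id"].astype(str)

        dup = df.duplicated(subset=["frame", "agent_id"])
        if dup.any():
            rows = list(np.flatnonzero(dup.to_numpy())[:10])
            raise ValueError(f"duplicate (frame, agent_id) pairs at rows {rows}")
        numeric = [c for c in ("x", "y", "vx", "vy") if c in df.columns]
        vals = df[numeric].to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            rows = list(np.flatnonzero(~np.all(np.isfinite(vals), axis=1))[:10])
            raise ValueError(f"non-finite values at rows {rows}")

        df = df.sort_values(["frame", "agent_id"], kind="stable").reset_index(drop=True)

        synthesized: tuple[str, ...] = ()
        if "vx" not in df.columns or "vy" not in df.columns:
            df, synthesized = _synthesize_velocities(df)
            log.info("synthesized velocities for %d agents", len(synthesized))

        runs = _presence_runs(df)
        return cls(df=df, synthesized_velocity_agents=synthesized, runs=runs)

    @property
    def frames(self) -> np.ndarray:
        return np.unique(self.df["frame"].to_numpy())

    def window(self, frame: int, depth: int):
        """Agents present for the ``depth`` frames ending at ``frame``.

        Returns ``(TrajectoryWindow, dropped_ids)`` where positions[s] /
        velocities[s] are the arrays ``s`` frames before ``frame``.  Agents
        missing any frame of the span are dropped and returned for logging.
        """
        start = frame - depth + 1
        keep, dropped = [], []
        for agent, spans in self.runs.items():
            if any(s <= start and frame <= e for s, e in spans):
                keep.append(agent)
            elif any(s <= frame <= e for s, e in spans):
                dropped.append(agent)
        if len(keep) < 2:
            raise ValueError(
                f"frame {frame}: only {len(keep)} agents have the required "
                f"{depth}-frame history"
            )
        keep = sorted(keep)
        sub = self.df[
            self.df["frame"].between(start, frame) & self.df["agent_id"].isin(keep)
        ]
        piv = sub.set_index(["frame", "agent_id"])
        n, d = len(keep), depth
        pos = np.empty((d, n, 2))
        vel = np.empty((d, n, 2))
        for s in range(d):
            block = piv.xs(frame - s, level="frame").loc[keep]
            pos[s] = block[["x", "y"]].to_numpy()
            vel[s] = block[["vx", "vy"]].to_numpy()
        if dropped:
            log.debug("frame %d: dropped agents with gaps: %s", frame, dropped)
        return (
            TrajectoryWindow(frame=frame, positions=pos, velocities=vel,
                             agent_ids=tuple(keep)),
            tuple(dropped),
        )


def _presence_runs(df: pd.DataFrame) -> dict:
    runs: dict = {}
    for agent, grp in df.groupby("agent_id", sort=False):
        f = np.sort(grp["frame"].to_numpy())
        breaks = np.flatnonzero(np.diff(f) != 1)
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks, [f.size - 1]])
        runs[agent] = [(int(f[s]), int(f[e])) for s, e in zip(starts, ends)]
    return runs


def _synthesize_velocities(df: pd.DataFrame):
    df = df.copy()
    df["vx"] = np.nan
    df["vy"] = np.nan
    agents = []
    for agent, grp in df.groupby("agent_id", sort=False):
        grp = grp.sort_values("frame")
        f = grp["frame"].to_numpy()
        breaks = np.flatnonzero(np.diff(f) != 1)
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks + 1, [f.size]])
        for s, e in zip(starts, ends):
            idx = grp.index[s:e]
            if e - s == 1:
                df.loc[idx, ["vx", "vy"]] = 0.0
                continue
            xy = grp[["x", "y"]].to_numpy()[s:e]
            v = np.gradient(xy, axis=0)
            df.loc[idx, "vx"] = v[:, 0]
            df.loc[idx, "vy"] = v[:, 1]
        agents.append(str(agent))
    return df, tuple(agents)


def read_trajectories(path, config=None) -> TrajectoryTable:
    """Read and validate a tidy trajectory CSV (``#`` lines are comments)."""
    df = pd.read_csv(path, comment="#")
    return TrajectoryTable.from_dataframe(df)


def write_trajectories(table, path, header_comments=()) -> None:
    """Write a TrajectoryTable (or tidy DataFrame) back to CSV."""
    df = table.df if isinstance(table, TrajectoryTable) else table
    with open(path, "w") as fh:
        for line in header_comments:
            fh.write(f"# {line}\n")
        df.to_csv(fh, index=False)
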