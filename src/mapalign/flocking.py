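"""Vicsek-type flocking simulator on the unit torus.

N agents move at a fixed speed v; at every step each agent adopts the
circular mean heading of all agents within toroidal distance r (itself
included, so the neighbor set is never empty) plus an independent Gaussian
angular noise draw N(0, eps^2).  Updates are synchronous.  The coupling
radius r(t) can follow a schedule — constant, a linear ramp between a low
and a high value, or a sinusoidal chirp — which drives the system between
incoherent motion and long-range order.

The global polarization (norm of the mean unit heading, in [0, 1]) serves
as the ground-truth order parameter; the experiment runner also evaluates
the map alignment statistic Z_k between the position metric and the
velocity-profile metric along the run, which is the quantity of interest
for detecting the onset of collective order without knowing the order
parameter in advance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import alignment, diffusion, metrics

__all__ = [
    "Schedule",
    "FlockConfig",
    "FlockState",
    "FlockRun",
    "TrialSummary",
    "step",
    "mean_velocity",
    "simulate",
    "run_experiment",
    "run_trials",
]


@dataclass(frozen=True)
class Schedule:
    """Coupling radius r(t), piecewise-defined for all steps.

    kinds:
      * ``constant`` — r = r0 throughout;
      * ``ramp`` — r0 until ``t_start``, linear to r1 over
        ``t_start .. t_end``, r1 afterwards;
      * ``chirp`` — sinusoid between r0 and r1 whose instantaneous
        frequency grows linearly from ``f0`` to ``f1`` cycles/step over
        ``duration`` steps.
    """

    kind: str = "constant"
    r0: float = 0.0065
    r1: float = 0.06
    t_start: int = 0
    t_end: int = 0
    f0: float = 0.0005
    f1: float = 0.005
    duration: int = 0

    def __post_init__(self):
        if self.kind not in ("constant", "ramp", "chirp"):
            raise ValueError(f"unknown schedule kind {self.kind!r}")
        if self.r0 < 0 or self.r1 < 0:
            raise ValueError("radii must be nonnegative")
        if self.kind == "ramp" and self.t_end < self.t_start:
            raise ValueError("ramp needs t_end >= t_start")

    @classmethod
    def constant(cls, r: float) -> "Schedule":
        return cls(kind="constant", r0=r, r1=r)

    @classmethod
    def ramp(cls, r0: float, r1: float, t_start: int, t_end: int) -> "Schedule":
        return cls(kind="ramp", r0=r0, r1=r1, t_start=t_start, t_end=t_end)

    @classmethod
    def chirp(cls, r0: float, r1: float, f0: float, f1: float, duration: int) -> "Schedule":
        return cls(kind="chirp", r0=r0, r1=r1, f0=f0, f1=f1, duration=duration)

    def r_at(self, t: int) -> float:
        if self.kind == "constant":
            return self.r0
        if self.kind == "ramp":
            if t <= self.t_start:
                return self.r0
            if t >= self.t_end:
                return self.r1
            frac = (t - self.t_start) / (self.t_end - self.t_start)
            return self.r0 + frac * (self.r1 - self.r0)
        # chirp: phase integrates a linearly increasing frequency
        dur = max(self.duration, 1)
        phase = self.f0 * t + 0.5 * (self.f1 - self.f0) * t**2 / dur
        mid = 0.5 * (self.r0 + self.r1)
        amp = 0.5 * (self.r1 - self.r0)
        return mid - amp * math.cos(2.0 * math.pi * phase)


@dataclass(frozen=True)
class FlockConfig:
    """Simulation settings; the classic regime is eps = pi/5, v = 1/320."""

    n_agents: int = 500
    speed: float = 1.0 / 320.0
    noise: float = math.pi / 5.0
    schedule: Schedule = field(default_factory=Schedule)
    n_steps: int = 2000
    seed: int = 0
    burn_in: int = 0
    aligned_start: bool = False

    def __post_init__(self):
        if self.n_agents < 2:
            raise ValueError("need at least 2 agents")
        if self.speed <= 0:
            raise ValueError("speed must be positive")
        if self.noise < 0:
            raise ValueError("noise SD must be nonnegative")


@dataclass(frozen=True)
class FlockState:
    """Positions on the unit torus and headings in [0, 2pi) at one step."""

    positions: np.ndarray
    headings: np.ndarray
    step_index: int = 0

    def __post_init__(self):
        p = np.mod(np.asarray(self.positions, dtype=float), 1.0)
        h = np.mod(np.asarray(self.headings, dtype=float), 2.0 * math.pi)
        if p.ndim != 2 or p.shape[1] != 2 or h.shape != (p.shape[0],):
            raise ValueError("positions must be (n, 2) and headings (n,)")
        object.__setattr__(self, "positions", p)
        object.__setattr__(self, "headings", h)

    @property
    def n(self) -> int:
        return self.positions.shape[0]

    def velocities(self, speed: float) -> np.ndarray:
        return speed * np.stack([np.cos(self.headings), np.sin(self.headings)], axis=1)


def _toroidal_sq_dists(p: np.ndarray) -> np.ndarray:
    delta = np.abs(p[:, None, :] - p[None, :, :])
    delta = np.minimum(delta, 1.0 - delta)
    return np.sum(delta**2, axis=-1)


def _step_with_noise(
    state: FlockState, r: float, v: float, noise_draws: np.ndarray
) -> FlockState:
    """Synchronous update with the per-agent angular noise supplied explicitly."""
    adj = _toroidal_sq_dists(state.positions) <= r * r  # includes self (0 <= r^2)
    ux = adj @ np.cos(state.headings)
    uy = adj @ np.sin(state.headings)
    new_h = np.arctan2(uy, ux) + noise_draws
    new_p = state.positions + v * np.stack([np.cos(new_h), np.sin(new_h)], axis=1)
    return FlockState(positions=new_p, headings=new_h, step_index=state.step_index + 1)


def step(
    state: FlockState,
    r: float,
    eps: float,
    v: float,
    rng: np.random.Generator,
) -> FlockState:
    """One synchronous Vicsek update.

    Each agent's new heading is the circular mean (angle of the summed unit
    heading vectors) of all agents within toroidal distance r, itself
    included, plus an independent N(0, eps^2) draw; it then moves distance v
    along the new heading, wrapping on the torus.
    """
    noise = eps * rng.standard_normal(state.n)
    return _step_with_noise(state, r, v, noise)


def mean_velocity(state: FlockState, v: float) -> tuple[np.ndarray, float]:
    """Mean velocity vector (speed times mean unit heading) and its magnitude."""
    u = np.stack([np.cos(state.headings), np.sin(state.headings)], axis=1).mean(axis=0)
    vec = v * u
    return vec, float(np.linalg.norm(vec))


def polarization(state: FlockState) -> float:
    """Norm of the mean unit heading vector, in [0, 1]."""
    u = np.stack([np.cos(state.headings), np.sin(state.headings)], axis=1).mean(axis=0)
    return float(np.linalg.norm(u))


def initial_state(cfg: FlockConfig, rng: np.random.Generator) -> FlockState:
    p = rng.random((cfg.n_agents, 2))
    if cfg.aligned_start:
        h = np.full(cfg.n_agents, float(rng.uniform(0.0, 2.0 * math.pi)))
    else:
        h = rng.uniform(0.0, 2.0 * math.pi, cfg.n_agents)
    return FlockState(positions=p, headings=h, step_index=0)


def simulate(cfg: FlockConfig, rng: np.random.Generator | None = None):
    """Run the model; returns (positions, headings, r_series).

    ``positions[t]`` / ``headings[t]`` hold the state after t update steps
    (index 0 is the initial condition), shapes ``(n_steps+1, n, 2)`` and
    ``(n_steps+1, n)``.  Burn-in steps at the schedule's initial radius are
    applied before recording starts.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    state = initial_state(cfg, rng)
    for _ in range(cfg.burn_in):
        state = step(state, cfg.schedule.r_at(0), cfg.noise, cfg.speed, rng)
        state = replace(state, step_index=0)
    T, n = cfg.n_steps, cfg.n_agents
    pos = np.empty((T + 1, n, 2))
    hdg = np.empty((T + 1, n))
    rs = np.empty(T + 1)
    pos[0], hdg[0], rs[0] = state.positions, state.headings, cfg.schedule.r_at(0)
    for t in range(1, T + 1):
        r = cfg.schedule.r_at(t - 1)
        state = step(state, r, cfg.noise, cfg.speed, rng)
        pos[t], hdg[t], rs[t] = state.positions, state.headings, r
    return pos, hdg, rs


@dataclass(frozen=True)
class FlockRun:
    """One simulation plus per-step diagnostics.

    ``z`` is NaN where the velocity-profile window extends past the start of
    the run or the step was skipped by the measurement stride.
    """

    config: FlockConfig
    positions: np.ndarray
    headings: np.ndarray
    r: np.ndarray
    order: np.ndarray
    z: np.ndarray


def run_experiment(
    cfg: FlockConfig,
    metric_cfg: metrics.MetricConfig | None = None,
    k: int = 10,
    k_nn: int = 7,
    z_stride: int = 1,
    measure_steps=None,
) -> FlockRun:
    """Simulate and measure the order parameter and Z_k(p, v) along the run.

    Z_k projects the position-metric diffusion modes onto the span of the
    velocity-profile-metric modes (forward direction).  It is evaluated at
    steps with at least ``window`` frames of history, restricted to
    ``measure_steps`` if given, else every ``z_stride``-th step.
    """
    if metric_cfg is None:
        metric_cfg = metrics.MetricConfig(window=10, tau=5.0, max_lag=0, geometry="torus")
    pos, hdg, rs = simulate(cfg)
    T = cfg.n_steps
    order = np.array(
        [polarization(FlockState(pos[t], hdg[t], t)) for t in range(T + 1)]
    )
    z = np.full(T + 1, np.nan)
    depth = metric_cfg.history_depth
    if measure_steps is None:
        measure_steps = range(depth, T + 1, z_stride)
    for t in measure_steps:
        if not depth <= t <= T:
            continue
        z[t] = _z_at_step(pos, hdg, t, cfg.speed, metric_cfg, k, k_nn)
    return FlockRun(config=cfg, positions=pos, headings=hdg, r=rs, order=order, z=z)


def _z_at_step(pos, hdg, t, speed, metric_cfg, k, k_nn) -> float:
    depth = metric_cfg.history_depth
    n = pos.shape[1]
    vel = np.empty((depth, n, 2))
    for s in range(depth):
        h = hdg[t - s]
        vel[s] = speed * np.stack([np.cos(h), np.sin(h)], axis=1)
    W = metrics.TrajectoryWindow(
        frame=t, positions=pos[t - depth + 1 : t + 1][::-1], velocities=vel,
        geometry="torus", period=1.0,
    )
    d1 = metrics.position_distance_matrix(pos[t], geometry="torus", period=1.0)
    if metric_cfg.max_lag > 0:
        d2 = metrics.lagged_velocity_distance_matrix(W, metric_cfg)
    else:
        d2 = metrics.velocity_profile_distance_matrix(W, metric_cfg)
    b1 = diffusion.spectral_decompose(diffusion.normalize_to_markov(
        diffusion.gknn_kernel(d1, k_nn=k_nn, distance_floor=True)))
    b2 = diffusion.spectral_decompose(diffusion.normalize_to_markov(
        diffusion.gknn_kernel(d2, k_nn=k_nn, distance_floor=True)))
    return alignment.map_alignment_statistic(b1, b2, k).z


@dataclass(frozen=True)
class TrialSummary:
    """Mean and empirical 90% band of order parameter and Z across trials."""

    r: np.ndarray
    order_mean: np.ndarray
    order_band: np.ndarray
    z_mean: np.ndarray
    z_band: np.ndarray
    runs: tuple[FlockRun, ...]


def run_trials(
    cfg: FlockConfig,
    n_trials: int,
    base_seed: int | None = None,
    **experiment_kwargs,
) -> TrialSummary:
    """Repeat the experiment across seeds and aggregate.

    Bands are the empirical 5th-95th percentile envelope across trials
    (NaN where no trial measured Z).
    """
    if base_seed is None:
        base_seed = cfg.seed
    runs = []
    for i in range(n_trials):
        runs.append(run_experiment(replace(cfg, seed=base_seed + i), **experiment_kwargs))
    order = np.stack([r.order for r in runs])
    zs = np.stack([r.z for r in runs])
    with np.errstate(invalid="ignore"):
        z_mean = np.nanmean(zs, axis=0)
        z_band = np.nanpercentile(zs, [5, 95], axis=0)
    return TrialSummary(
        r=runs[0].r,
        order_mean=order.mean(axis=0),
        order_band=np.percentile(order, [5, 95], axis=0),
        z_mean=z_mean,
        z_band=z_band,
        runs=tuple(runs),
    )
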