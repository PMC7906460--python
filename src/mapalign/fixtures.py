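"""Synthetic fish-school-like sessions with known regime labels.

The empirical schooling data this package is designed for (tracked fish in
a shallow tank, ~70-280 individuals visible at a time, 30 fps) is not
distributable, so this module generates kinematic stand-ins with
unambiguous ground truth.  The generators are deliberately *not* the
Vicsek simulator: regimes are imposed kinematically so that the labels are
independent of the method under test.

Regimes (named for the O_p / O_r demarcation they occupy):

* ``milling`` — noisy circular orbits around a common center (low
  polarization, high rotation);
* ``swarm`` — independent jittered random walks with near-zero net motion
  (both low);
* ``polarized-single`` — one group with a common drifting heading whose
  agent-level heading fluctuations follow a smooth *spatial* field, so the
  velocity geometry is genuinely organized by position, as in a real
  school (high polarization, low rotation);
* ``polarized-split`` — two subgroups with slightly different mean
  headings and independent heading fields, spatially overlapping at first
  and slowly diverging: the velocity network splits macroscopically while
  the position network only partially does, the signature of beta-style
  (multi-subgroup) polarized motion.

Velocities are stored as central finite differences of the positions
(forward/backward at the ends), exactly matching ``numpy.gradient``, so a
reader re-deriving velocities from positions reproduces them bit-for-bit.
Each generator self-checks that >= 90% of its frames land in the intended
order-parameter box and regenerates with a fresh substream otherwise
(bounded retries).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .macrostate import order_parameters

__all__ = ["RegimeSpec", "Segment", "Session", "make_regime", "make_session", "standard_session"]

REGIMES = ("milling", "swarm", "polarized-single", "polarized-split")

#: O_p/O_r box each regime must occupy (min_op, max_op, min_or, max_or)
_BOXES = {
    "milling": (0.0, 0.35, 0.65, 1.0),
    "swarm": (0.0, 0.35, 0.0, 0.35),
    "polarized-single": (0.65, 1.0, 0.0, 0.35),
    "polarized-split": (0.65, 1.0, 0.0, 0.35),
}


@dataclass(frozen=True)
class RegimeSpec:
    """One labeled segment to generate.

    Motion parameters are in arena units (roughly meters) and frames; the
    frame rate is fixed at 30 fps so a 2 s lag is 60 frames.  ``n`` should
    stay in the 70-280 range the empirical group size fluctuates over.
    """

    regime: str
    n: int = 150
    duration: int = 150
    speed: float = 0.02
    angular_speed: float = 0.04
    heading_noise: float = 0.05
    field_amplitude: float = 0.25
    field_wavelength: float = 2.4
    n_subgroups: int = 2
    heading_offset: float = np.pi / 6
    weave_period: float = 100.0
    speed_field_amplitude: float = 0.3
    # the beta-style split regime is *defined* by a lower level of internal
    # organization: weaker spatial fields, noisier headings
    split_field_scale: float = 1.0 / 3.0
    split_heading_noise: float = 0.12
    equal_spacing: bool = False
    n_range: tuple[int, int] = (70, 280)
    max_retries: int = 5

    def __post_init__(self):
        if self.regime not in REGIMES:
            raise ValueError(f"unknown regime {self.regime!r}; choose from {REGIMES}")
        lo, hi = self.n_range
        if not lo <= self.n <= hi:
            raise ValueError(f"n = {self.n} outside configured range {self.n_range}")
        if self.duration < 70:
            raise ValueError("duration must cover at least window + max lag (70 frames)")


@dataclass(frozen=True)
class Segment:
    """Generated trajectory for one regime: (T, n, 2) positions/velocities."""

    spec: RegimeSpec
    positions: np.ndarray
    velocities: np.ndarray
    box_fraction: float

    @property
    def regime(self) -> str:
        return self.spec.regime

    @property
    def duration(self) -> int:
        return self.positions.shape[0]

    @property
    def n(self) -> int:
        return self.positions.shape[1]


@dataclass(frozen=True)
class Session:
    """Concatenated regime segments with ground-truth per-frame labels.

    Agent sets are fresh per segment (new ids), emulating fish entering and
    leaving the field of view, so the group size fluctuates across segments
    and analysis windows never span a regime switch.
    """

    segments: tuple[Segment, ...]
    labels: pd.DataFrame = field(repr=False)  # columns: frame, true_regime
    trajectory: pd.DataFrame = field(repr=False)  # tidy frame/agent_id/x/y/vx/vy

    @property
    def n_frames(self) -> int:
        return int(self.labels.shape[0])


def _finite_diff_velocities(pos: np.ndarray) -> np.ndarray:
    """Central differences in time, forward/backward at the ends (np.gradient)."""
    return np.gradient(pos, axis=0)


def _gen_milling(spec: RegimeSpec, rng: np.random.Generator) -> np.ndarray:
    n, T = spec.n, spec.duration
    center = np.array([1.0, 1.0])
    if spec.equal_spacing:
        ang = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
        rad = np.full(n, 0.45)
    else:
        ang = rng.uniform(0.0, 2.0 * np.pi, n)
        rad = rng.uniform(0.3, 0.6, n)
    base_rad = rad.copy()
    noise = spec.heading_noise
    pos = np.empty((T, n, 2))
    for t in range(T):
        pos[t] = center + rad[:, None] * np.stack([np.cos(ang), np.sin(ang)], axis=1)
        ang = ang + spec.angular_speed + 0.1 * noise * rng.standard_normal(n)
        rad = rad + 0.05 * (base_rad - rad) + 0.04 * noise * rng.standard_normal(n)
    return pos


def _gen_swarm(spec: RegimeSpec, rng: np.random.Generator) -> np.ndarray:
    n, T = spec.n, spec.duration
    pos = np.empty((T, n, 2))
    p = rng.normal(scale=0.35, size=(n, 2))
    for t in range(T):
        pos[t] = p
        theta = rng.uniform(0.0, 2.0 * np.pi, n)
        speed = np.abs(rng.normal(scale=0.4 * spec.speed, size=n))
        p = p + speed[:, None] * np.stack([np.cos(theta), np.sin(theta)], axis=1)
    return pos


def _heading_field(offsets: np.ndarray, u: np.ndarray, wavelength: float, phase: float) -> np.ndarray:
    proj = offsets @ u
    return np.sin(2.0 * np.pi * proj / wavelength + phase)


def _gen_polarized(spec: RegimeSpec, rng: np.random.Generator, split: bool) -> np.ndarray:
    n, T = spec.n, spec.duration
    if split:
        m = spec.n_subgroups
        group = np.sort(rng.integers(0, m, n))
        # weave: subgroups oscillate around the common heading in antiphase,
        # following distinct paths while staying spatially intermingled
        deltas = (np.arange(m) - (m - 1) / 2.0) * 2.0 * spec.heading_offset / max(m - 1, 1)
        weave_period = spec.weave_period
        field_amp = spec.field_amplitude * spec.split_field_scale
        speed_amp = spec.speed_field_amplitude * spec.split_field_scale
        heading_noise = spec.split_heading_noise
    else:
        m = 1
        group = np.zeros(n, dtype=int)
        deltas = np.zeros(1)
        weave_period = np.inf
        field_amp = spec.field_amplitude
        speed_amp = spec.speed_field_amplitude
        heading_noise = spec.heading_noise

    theta0 = float(rng.uniform(0.0, 2.0 * np.pi))
    perp = np.array([-np.sin(theta0), np.cos(theta0)])
    direction = np.array([np.cos(theta0), np.sin(theta0)])
    along = rng.normal(scale=0.4, size=n)
    across = rng.normal(scale=0.2, size=n)
    p = along[:, None] * direction + across[:, None] * perp

    # each subgroup carries a pair of smooth spatial fields tied to its
    # motion: headings vary front-to-back (leaders/followers) and speeds
    # vary laterally (flank bands), so the velocity geometry is genuinely
    # organized by position within a subgroup — with independent phases per
    # subgroup, mismatched across subgroups
    u_g = [direction for _ in range(m)]
    u2_g = [perp for _ in range(m)]
    phase_g = rng.uniform(0.0, 2.0 * np.pi, m)
    phase2_g = rng.uniform(0.0, 2.0 * np.pi, m)
    weave_phase = float(rng.uniform(0.0, 2.0 * np.pi))

    pos = np.empty((T, n, 2))
    for t in range(T):
        pos[t] = p
        theta0 += 0.01 * rng.standard_normal()
        headings = np.empty(n)
        centroid = p.mean(axis=0)
        weave = np.sin(2.0 * np.pi * t / weave_period + weave_phase) if split else 0.0
        speeds = np.empty(n)
        for g in range(m):
            sel = group == g
            off = p[sel] - centroid
            fld = _heading_field(off, u_g[g], spec.field_wavelength, phase_g[g])
            fld2 = _heading_field(off, u2_g[g], spec.field_wavelength, phase2_g[g])
            headings[sel] = theta0 + weave * deltas[g] + field_amp * fld
            speeds[sel] = spec.speed * (1.0 + speed_amp * fld2)
        headings += heading_noise * rng.standard_normal(n)
        speeds *= 1.0 + 0.05 * rng.standard_normal(n)
        p = p + speeds[:, None] * np.stack([np.cos(headings), np.sin(headings)], axis=1)
        phase_g = phase_g + 0.02 * rng.standard_normal(m)
        phase2_g = phase2_g + 0.02 * rng.standard_normal(m)
    return pos


_GENERATORS = {
    "milling": _gen_milling,
    "swarm": _gen_swarm,
    "polarized-single": lambda s, r: _gen_polarized(s, r, split=False),
    "polarized-split": lambda s, r: _gen_polarized(s, r, split=True),
}


def _box_fraction(pos: np.ndarray, vel: np.ndarray, regime: str) -> float:
    lo_p, hi_p, lo_r, hi_r = _BOXES[regime]
    T = pos.shape[0]
    ok = 0
    for t in range(T):
        op = order_parameters(pos[t], vel[t], frame=t)
        if lo_p <= op.o_p <= hi_p and lo_r <= op.o_r <= hi_r:
            ok += 1
    return ok / T


def make_regime(spec: RegimeSpec, rng: np.random.Generator) -> Segment:
    """Generate one labeled segment, self-checked against its O_p/O_r box.

    At least 90% of frames must land in the regime's order-parameter box;
    otherwise the segment is regenerated from a fresh substream, up to
    ``spec.max_retries`` times, after which a ValueError reports the
    achieved fractions.
    """
    achieved = []
    for _ in range(spec.max_retries):
        pos = _GENERATORS[spec.regime](spec, rng)
        vel = _finite_diff_velocities(pos)
        frac = _box_fraction(pos, vel, spec.regime)
        achieved.append(frac)
        if frac >= 0.9:
            return Segment(spec=spec, positions=pos, velocities=vel, box_fraction=frac)
    raise ValueError(
        f"could not generate a {spec.regime!r} segment meeting its order-parameter "
        f"box in >= 90% of frames after {spec.max_retries} tries; achieved "
        f"fractions: {[f'{a:.2f}' for a in achieved]}"
    )


def make_session(specs, rng: np.random.Generator) -> Session:
    """Concatenate regimes into one session with fresh agents per segment."""
    specs = list(specs)
    if not specs:
        raise ValueError("need at least one regime spec")
    segments = [make_regime(s, rng) for s in specs]
    rows = []
    label_rows = []
    frame0 = 0
    for si, seg in enumerate(segments):
        ids = [f"s{si}_{i}" for i in range(seg.n)]
        for t in range(seg.duration):
            f = frame0 + t
            label_rows.append((f, seg.regime))
            for i, aid in enumerate(ids):
                rows.append(
                    (f, aid, seg.positions[t, i, 0], seg.positions[t, i, 1],
                     seg.velocities[t, i, 0], seg.velocities[t, i, 1])
                )
        frame0 += seg.duration
    traj = pd.DataFrame(rows, columns=["frame", "agent_id", "x", "y", "vx", "vy"])
    labels = pd.DataFrame(label_rows, columns=["frame", "true_regime"])
    return Session(segments=tuple(segments), labels=labels, trajectory=traj)


def standard_session(
    rng: np.random.Generator,
    duration: int = 150,
    n_range: tuple[int, int] = (70, 280),
    order=("milling", "swarm", "polarized-single", "polarized-split"),
) -> Session:
    """One segment per regime, modeling one school with fluctuating visibility.

    Segment group sizes share a session-level base count (the school) with
    +/- 25% per-segment fluctuation (fish entering and leaving the tracked
    field of view), all within ``n_range``.
    """
    lo, hi = n_range
    base = float(rng.uniform(lo, hi))
    specs = []
    for r in order:
        n = int(round(base * rng.uniform(0.75, 1.25)))
        specs.append(RegimeSpec(regime=r, n=int(np.clip(n, lo, hi)),
                                duration=duration, n_range=n_range))
    return make_session(specs, rng)
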