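"""Time integration of the evacuation: agents, configuration, run loops.

Newton's second law is integrated per agent with semi-implicit Euler; the
total force is the sum of pair and wall contact forces plus the psychological
force toward the agent's desired velocity.  The decision layer (desired
velocities) updates every calculation time step ``dt``; contact physics runs
on ``n_substeps`` sub-steps within each ``dt`` because the stiff contact
springs demand a shorter stable step than the decision cadence.

Body orientation relaxes toward the direction of motion (major axis along the
heading) with the rotation time constant rather than integrating a moment
equation; the finite relaxation keeps the boundary displacement caused by
rotation small per sub-step so contact springs resolve it.  Agents whose
center crosses the exit line are marked exited with a linearly interpolated
exit time and removed from the dynamics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from . import _kernels
from .arena import Arena, build_arena
from .behavior import AgentTraits, BehaviorConfig, assign_handedness, desired_velocities
from .errors import IntegrationError, InvalidGeometryError, PlacementError
from .forces import ContactParams
from .geometry import EllipseShape

__all__ = [
    "AgentState",
    "SimConfig",
    "RunResult",
    "SweepResult",
    "DEFAULT_SMICE_PROFILE",
    "sample_desired_speeds",
    "step",
    "run",
    "sweep",
]

#: Bundled per-angle standard deviations of desired speed (m/s), monotone
#: decreasing with the guide-wall angle: dispersion shrinks as the walls
#: enforce lane formation.  The uniform mode replaces every entry by the mean
#: of these six values.
DEFAULT_SMICE_PROFILE: dict[float, float] = {
    0.0: 0.12,
    15.0: 0.10,
    30.0: 0.08,
    45.0: 0.06,
    60.0: 0.045,
    75.0: 0.03,
}

TRACK_COLUMNS = [
    "trial_id",
    "frame",
    "time_s",
    "agent_id",
    "x_m",
    "y_m",
    "orientation_rad",
    "vx_mps",
    "vy_mps",
    "status",
]
EVENT_COLUMNS = ["trial_id", "agent_id", "exit_time_s"]


@dataclass
class AgentState:
    """One agent's kinematics, shape, traits and evacuation status."""

    id: int
    shape: EllipseShape
    mass: float
    velocity: tuple[float, float]
    traits: AgentTraits
    status: str = "waiting"  # waiting -> evacuating -> exited
    exit_time: float | None = None

    def __post_init__(self):
        if self.mass <= 0.0:
            raise ValueError("mass must be positive")
        if self.status not in ("waiting", "evacuating", "exited"):
            raise ValueError(f"unknown status {self.status!r}")
        if (self.exit_time is None) == (self.status == "exited"):
            raise ValueError("exit_time must be set iff status == 'exited'")


@dataclass(frozen=True)
class SimConfig:
    """Full configuration of one simulation run (mouse-scale defaults)."""

    n_agents: int = 20
    angle_deg: float = 0.0
    dt: float = 1.0e-3
    n_substeps: int = 4
    max_time: float = 60.0
    seed: int = 0
    speed_mean: float = 0.4
    speed_sd: float = 0.08
    mass: float = 0.030
    semi_major: float = 0.03
    semi_minor: float = 0.015
    response_time: float = 0.1
    rotation_time: float = 0.1
    record_stride: int = 33
    contact: ContactParams = field(default_factory=ContactParams)
    behavior: BehaviorConfig | None = None
    room_width: float = 0.4
    room_length: float = 0.6
    exit_width: float = 0.06
    guide_length: float = 0.15
    waiting_depth: float = 0.25

    def __post_init__(self):
        if self.dt <= 0.0 or self.n_substeps < 1:
            raise ValueError("dt must be positive and n_substeps >= 1")
        if self.n_agents < 1:
            raise ValueError("n_agents must be positive")
        if self.speed_sd < 0.0 or self.speed_mean <= 0.0:
            raise ValueError("speed_mean must be positive and speed_sd >= 0")
        if self.response_time <= 0.0 or self.rotation_time <= 0.0:
            raise ValueError("response_time and rotation_time must be positive")

    def behavior_config(self) -> BehaviorConfig:
        if self.behavior is not None:
            return self.behavior
        return BehaviorConfig(
            sector_radius=4.0 * self.semi_major,
            wall_avoid_distance=2.0 * self.semi_minor,
        )

    def build_arena(self) -> Arena:
        return build_arena(
            self.angle_deg,
            room_width=self.room_width,
            room_length=self.room_length,
            exit_width=self.exit_width,
            guide_length=self.guide_length,
            waiting_depth=self.waiting_depth,
        )


@dataclass(frozen=True)
class RunResult:
    """Trajectories (one row per recorded frame and agent) and exit events."""

    tracks: pd.DataFrame
    events: pd.DataFrame
    config: SimConfig
    arena: Arena


@dataclass(frozen=True)
class SweepResult:
    """Pooled output of an angle x case sweep."""

    tracks: pd.DataFrame
    events: pd.DataFrame
    trials: pd.DataFrame


def sample_desired_speeds(mean: float, sd: float, n: int, rng) -> np.ndarray:
    """``n`` normal draws with the given mean and sd, redrawn until positive."""
    if mean <= 0.0 or sd < 0.0:
        raise ValueError("mean must be positive and sd non-negative")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    out = rng.normal(mean, sd, size=n)
    bad = out <= 0.0
    while np.any(bad):
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = out <= 0.0
    return out


def _place_agents(arena: Arena, config: SimConfig, rng) -> np.ndarray:
    """Seeded rejection sampling of non-overlapping start positions in the
    waiting area; all agents initially face the exit (major axis along +y),
    so non-overlap reduces to unit-disk separation in axis-scaled coordinates."""
    a, b = config.semi_major, config.semi_minor
    eps = 1e-3
    x_lo, x_hi = b + eps, arena.width - b - eps
    y_lo, y_hi = a + eps, arena.waiting_depth - a - eps
    if x_hi <= x_lo or y_hi <= y_lo:
        raise PlacementError("waiting area too small for the agent body")
    placed = np.empty((config.n_agents, 2))
    for i in range(config.n_agents):
        for _ in range(20000):
            x = rng.uniform(x_lo, x_hi)
            y = rng.uniform(y_lo, y_hi)
            if i == 0:
                placed[i] = (x, y)
                break
            dx = (placed[:i, 0] - x) / b
            dy = (placed[:i, 1] - y) / a
            if np.all(dx * dx + dy * dy >= 4.0001):
                placed[i] = (x, y)
                break
        else:
            raise PlacementError(
                f"could not place {config.n_agents} non-overlapping agents; "
                "use a larger waiting area"
            )
    return placed


class _Engine:
    """Array-of-struct state plus the compiled step kernel."""

    def __init__(self, arena: Arena, config: SimConfig, rng: np.random.Generator):
        n = config.n_agents
        if arena.exit_width <= 2.0 * config.semi_minor:
            raise InvalidGeometryError("exit narrower than the agent minor diameter")
        self.arena = arena
        self.config = config
        self.behavior = config.behavior_config()
        self.pos = _place_agents(arena, config, rng)
        self.vel = np.zeros((n, 2))
        self.phi = np.full(n, math.pi / 2.0)
        self.active = np.ones(n, dtype=bool)
        self.exit_time = np.full(n, np.nan)
        self.speeds = sample_desired_speeds(config.speed_mean, config.speed_sd, n, rng)
        self.right_first = assign_handedness(
            n, self.behavior.right_first_fraction, rng
        )
        self.walls = arena.walls_array()
        self.pair_stretch = np.zeros((n, n, 2))
        self.wall_stretch = np.zeros((n, len(arena.walls), 2))
        m_eff_pair = config.mass / 2.0
        self.eta_pair = config.contact.damping(m_eff_pair)
        self.eta_wall = config.contact.damping(config.mass)
        self.gain = config.mass / config.response_time
        self.time = 0.0
        self.step_index = 0

    def desired(self) -> np.ndarray:
        des = np.zeros_like(self.pos)
        idx = np.nonzero(self.active)[0]
        if len(idx):
            des[idx] = desired_velocities(
                self.pos[idx],
                self.vel[idx],
                self.speeds[idx],
                self.right_first[idx],
                self.arena,
                self.behavior,
            )
        return des

    def advance(self, des_vel: np.ndarray | None = None, psych: bool = True):
        cfg = self.config
        if des_vel is None:
            des_vel = self.desired()
        bad = _kernels.advance(
            self.pos,
            self.vel,
            self.phi,
            self.active,
            self.exit_time,
            cfg.semi_major,
            cfg.semi_minor,
            cfg.mass,
            self.gain if psych else 0.0,
            des_vel,
            self.walls,
            self.arena.exit_p1[0],
            self.arena.exit_p2[0],
            self.arena.exit_p1[1],
            True,
            cfg.contact.k_normal,
            cfg.contact.k_tangential,
            cfg.contact.friction,
            self.eta_pair,
            self.eta_wall,
            self.pair_stretch,
            self.wall_stretch,
            self.time,
            cfg.dt,
            cfg.n_substeps,
            cfg.rotation_time,
        )
        if bad >= 0:
            raise IntegrationError(int(bad), self.step_index)
        self.time += cfg.dt
        self.step_index += 1


def _states_to_engine(states: Sequence[AgentState], arena: Arena, config: SimConfig) -> _Engine:
    for s in states:
        if s.shape.a != config.semi_major or s.shape.b != config.semi_minor:
            raise ValueError(
                "agent shapes must match config.semi_major/semi_minor: "
                f"agent {s.id} has a={s.shape.a}, b={s.shape.b}"
            )
    eng = _Engine.__new__(_Engine)
    n = len(states)
    eng.arena = arena
    eng.config = replace(config, n_agents=n)
    eng.behavior = config.behavior_config()
    eng.pos = np.array([s.shape.center for s in states], dtype=float).reshape(n, 2)
    eng.vel = np.array([s.velocity for s in states], dtype=float).reshape(n, 2)
    eng.phi = np.array([s.shape.orientation for s in states], dtype=float)
    eng.active = np.array([s.status != "exited" for s in states])
    eng.exit_time = np.array(
        [np.nan if s.exit_time is None else s.exit_time for s in states]
    )
    eng.speeds = np.array([s.traits.desired_speed for s in states])
    eng.right_first = np.array([s.traits.right_first for s in states])
    eng.walls = arena.walls_array()
    eng.pair_stretch = np.zeros((n, n, 2))
    eng.wall_stretch = np.zeros((n, len(arena.walls), 2))
    eng.eta_pair = config.contact.damping(config.mass / 2.0)
    eng.eta_wall = config.contact.damping(config.mass)
    eng.gain = config.mass / config.response_time
    eng.time = 0.0
    eng.step_index = 0
    return eng


def step(
    states: Sequence[AgentState], arena: Arena, config: SimConfig, psych: bool = True
) -> list[AgentState]:
    """Advance a list of agents by one decision step ``config.dt``.

    Convenience wrapper over the array engine for unit-scale experiments;
    tangential contact history does not persist across calls.  Set
    ``psych=False`` to integrate pure contact dynamics.
    """
    eng = _states_to_engine(states, arena, config)
    eng.advance(psych=psych)
    out = []
    for i, s in enumerate(states):
        exited = not eng.active[i]
        out.append(
            replace(
                s,
                shape=EllipseShape(
                    tuple(eng.pos[i]), float(eng.phi[i]), s.shape.a, s.shape.b
                ),
                velocity=tuple(eng.vel[i]),
                status="exited" if exited else "evacuating",
                exit_time=float(eng.exit_time[i]) if exited else None,
            )
        )
    return out


def run(config: SimConfig, arena: Arena | None = None, trial_id: str = "trial0") -> RunResult:
    """Run one evacuation to completion (or ``max_time``).

    Agents are placed without overlap in the waiting area, desired speeds
    sampled and handedness assigned from the run seed; the loop alternates
    behaviour updates and physics steps, recording a trajectory frame every
    ``record_stride`` steps.  Fully reproducible from the seed.
    """
    if arena is None:
        arena = config.build_arena()
    rng = np.random.default_rng(config.seed)
    eng = _Engine(arena, config, rng)

    rows: list[tuple] = []
    frame = 0

    def record():
        for i in np.nonzero(eng.active)[0]:
            rows.append(
                (
                    trial_id,
                    frame,
                    eng.time,
                    int(i),
                    eng.pos[i, 0],
                    eng.pos[i, 1],
                    eng.phi[i],
                    eng.vel[i, 0],
                    eng.vel[i, 1],
                    "evacuating",
                )
            )

    record()
    n_steps = int(round(config.max_time / config.dt))
    for k in range(n_steps):
        eng.advance()
        if (k + 1) % config.record_stride == 0:
            frame += 1
            record()
        if not eng.active.any():
            break

    tracks = pd.DataFrame(rows, columns=TRACK_COLUMNS)
    exited = np.nonzero(~eng.active)[0]
    order = np.argsort(eng.exit_time[exited], kind="stable")
    events = pd.DataFrame(
        {
            "trial_id": trial_id,
            "agent_id": exited[order].astype(int),
            "exit_time_s": eng.exit_time[exited][order],
        },
        columns=EVENT_COLUMNS,
    )
    return RunResult(tracks=tracks, events=events, config=config, arena=arena)


def sweep(
    base: SimConfig,
    angles: Sequence[float] = tuple(DEFAULT_SMICE_PROFILE),
    cases: int = 3,
    mode: str = "smice",
    sd_profile: dict[float, float] | None = None,
    seed: int = 0,
) -> SweepResult:
    """Run ``cases`` seeded trials at each guide-wall angle.

    ``mode='smice'`` applies the angle-specific desired-speed standard
    deviation from ``sd_profile``; ``mode='uniform'`` applies the across-angle
    mean of the profile at every angle.  Trial seeds derive from ``seed`` via
    a spawned seed sequence, so the sweep is reproducible end to end.
    """
    if mode not in ("smice", "uniform"):
        raise ValueError("mode must be 'smice' or 'uniform'")
    profile = dict(DEFAULT_SMICE_PROFILE if sd_profile is None else sd_profile)
    missing = [a for a in angles if a not in profile]
    if missing:
        raise ValueError(f"sd_profile lacks angles {missing}")
    sd_uni = float(np.mean([profile[a] for a in angles]))

    child_seeds = np.random.SeedSequence(seed).generate_state(len(angles) * cases)
    all_tracks, all_events, trial_rows = [], [], []
    idx = 0
    for angle in angles:
        sd = profile[angle] if mode == "smice" else sd_uni
        for case in range(cases):
            run_seed = int(child_seeds[idx] % (2**31))
            idx += 1
            cfg = replace(base, angle_deg=float(angle), speed_sd=sd, seed=run_seed)
            trial = f"a{angle:g}_c{case}"
            res = run(cfg, trial_id=trial)
            all_tracks.append(res.tracks)
            all_events.append(res.events)
            trial_rows.append(
                (trial, float(angle), case, run_seed, mode, base.n_agents)
            )
    return SweepResult(
        tracks=pd.concat(all_tracks, ignore_index=True),
        events=pd.concat(all_events, ignore_index=True),
        trials=pd.DataFrame(
            trial_rows,
            columns=["trial_id", "angle_deg", "case", "seed", "mode", "n_agents"],
        ),
    )
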