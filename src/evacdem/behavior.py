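"""Panic-state behavioural rules that set each agent's desired velocity.

Every agent rushes toward the exit.  When a slower agent blocks the front
sector, the agent tries to overtake by steering into a side sector (half-width
pi/6, checked in handedness order: most agents probe the +pi/6 side first)
provided that sector's occupant density is below a critical density; if both
side sectors are too crowded the agent slows down and follows the blocker.
Agents additionally steer away from any wall closer than a clearance distance.

Densities are counted over circular sectors of angular half-width pi/6 rotated
by {0, +pi/6, -pi/6} from the agent's exit-bound heading; the sector area is
``pi R^2 / 6``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np

__all__ = [
    "BehaviorConfig",
    "AgentTraits",
    "assign_handedness",
    "sector_density",
    "desired_velocity",
    "desired_velocities",
]

SECTOR_HALF_WIDTH = math.pi / 6.0

_SIDE_OFFSETS = {"front": 0.0, "right": SECTOR_HALF_WIDTH, "left": -SECTOR_HALF_WIDTH}


@dataclass(frozen=True)
class BehaviorConfig:
    """Tunables of the decision layer.

    ``critical_density`` is the sector occupancy (agents/m^2) above which a
    sector is rejected; the mouse-scale default 77 m^-2 corresponds to ~11%
    body-area coverage, the analogue of the human-scale 0.78 m^-2 threshold.
    ``sector_radius`` defaults to four semi-major axes; ``wall_avoid_distance``
    to two semi-minor axes.
    """

    critical_density: float = 77.0
    sector_radius: float = 0.12
    right_first_fraction: float = 0.9
    wall_avoid_distance: float = 0.03
    sector_offset: float = SECTOR_HALF_WIDTH

    def __post_init__(self):
        if self.critical_density <= 0.0 or self.sector_radius <= 0.0:
            raise ValueError("critical_density and sector_radius must be positive")
        if not (0.0 <= self.right_first_fraction <= 1.0):
            raise ValueError("right_first_fraction must lie in [0, 1]")

    @property
    def sector_area(self) -> float:
        return (math.pi / 3.0) * self.sector_radius**2 / 2.0


@dataclass(frozen=True)
class AgentTraits:
    """Handedness (which side sector is probed first) and desired speed."""

    right_first: bool
    desired_speed: float

    def __post_init__(self):
        if self.desired_speed <= 0.0:
            raise ValueError("desired_speed must be positive")


def assign_handedness(n: int, fraction_right: float, rng) -> np.ndarray:
    """Boolean right-first flags for ``n`` agents: exactly
    ``round(fraction_right * n)`` are right-first, in seeded shuffled order."""
    if n < 0:
        raise ValueError("n must be non-negative")
    if not (0.0 <= fraction_right <= 1.0):
        raise ValueError("fraction_right must lie in [0, 1]")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    n_right = int(round(fraction_right * n))
    flags = np.zeros(n, dtype=bool)
    flags[:n_right] = True
    rng.shuffle(flags)
    return flags


def _rel_angles(offsets: np.ndarray, heading: float) -> np.ndarray:
    ang = np.arctan2(offsets[:, 1], offsets[:, 0]) - heading
    return (ang + math.pi) % (2.0 * math.pi) - math.pi


def sector_density(
    agent_position,
    heading: float,
    side: Literal["front", "right", "left"],
    others,
    config: BehaviorConfig,
) -> float:
    """Occupant density (agents/m^2) of the circular sector on the given side.

    The sector axis is the heading rotated by 0 (front), +pi/6 (right) or
    -pi/6 (left); agents whose centers fall within angular half-width pi/6 and
    range ``sector_radius`` are counted.
    """
    others = np.asarray(others, dtype=float).reshape(-1, 2)
    if len(others) == 0:
        return 0.0
    off = others - np.asarray(agent_position, dtype=float)
    dist = np.hypot(off[:, 0], off[:, 1])
    axis = heading + _SIDE_OFFSETS[side] * (config.sector_offset / SECTOR_HALF_WIDTH)
    rel = _rel_angles(off, axis)
    count = int(
        np.sum((dist <= config.sector_radius) & (np.abs(rel) <= SECTOR_HALF_WIDTH) & (dist > 0.0))
    )
    return count / config.sector_area


def desired_velocities(
    positions,
    velocities,
    desired_speeds,
    right_first,
    arena,
    config: BehaviorConfig,
) -> np.ndarray:
    """Desired velocities for all agents at once (vectorized decision layer).

    Parameters mirror :func:`desired_velocity`; ``positions``/``velocities``
    are (N, 2), ``desired_speeds`` (N,), ``right_first`` boolean (N,).
    """
    pos = np.asarray(positions, dtype=float).reshape(-1, 2)
    vel = np.asarray(velocities, dtype=float).reshape(-1, 2)
    spd = np.asarray(desired_speeds, dtype=float).ravel()
    rf = np.asarray(right_first, dtype=bool).ravel()
    n = len(pos)
    if n == 0:
        return np.zeros((0, 2))

    target = np.asarray(arena.exit_target, dtype=float)
    to_exit = target[None, :] - pos
    d_exit = np.hypot(to_exit[:, 0], to_exit[:, 1])
    d_exit = np.where(d_exit < 1e-12, 1.0, d_exit)
    base = to_exit / d_exit[:, None]
    heading = np.arctan2(base[:, 1], base[:, 0])

    # pairwise geometry relative to each agent's exit-bound heading
    off = pos[None, :, :] - pos[:, None, :]          # off[i, j] = p_j - p_i
    dist = np.hypot(off[:, :, 0], off[:, :, 1])
    np.fill_diagonal(dist, np.inf)
    rel = np.arctan2(off[:, :, 1], off[:, :, 0]) - heading[:, None]
    rel = (rel + math.pi) % (2.0 * math.pi) - math.pi
    in_range = dist <= config.sector_radius

    front = in_range & (np.abs(rel) <= SECTOR_HALF_WIDTH)
    right = in_range & (np.abs(rel - config.sector_offset) <= SECTOR_HALF_WIDTH)
    left = in_range & (np.abs(rel + config.sector_offset) <= SECTOR_HALF_WIDTH)

    speeds_now = np.hypot(vel[:, 0], vel[:, 1])
    # nearest agent in the front sector
    d_front = np.where(front, dist, np.inf)
    tgt = np.argmin(d_front, axis=1)
    has_tgt = np.isfinite(d_front[np.arange(n), tgt])
    tgt_speed = speeds_now[tgt]
    overtake = has_tgt & (tgt_speed < speeds_now)

    dens_r = right.sum(axis=1) / config.sector_area
    dens_l = left.sum(axis=1) / config.sector_area
    rho_c = config.critical_density

    pref_open = np.where(rf, dens_r, dens_l) < rho_c
    other_open = np.where(rf, dens_l, dens_r) < rho_c

    rot = np.zeros(n)
    use_pref = overtake & pref_open
    use_other = overtake & ~pref_open & other_open
    follow = overtake & ~pref_open & ~other_open
    rot[use_pref] = np.where(rf[use_pref], config.sector_offset, -config.sector_offset)
    rot[use_other] = np.where(rf[use_other], -config.sector_offset, config.sector_offset)

    ang = heading + rot
    direction = np.stack((np.cos(ang), np.sin(ang)), axis=-1)
    speed_out = spd.copy()

    if np.any(follow):
        idx = np.nonzero(follow)[0]
        tj = tgt[idx]
        to_tgt = pos[tj] - pos[idx]
        d = np.hypot(to_tgt[:, 0], to_tgt[:, 1])
        d = np.where(d < 1e-12, 1.0, d)
        direction[idx] = to_tgt / d[:, None]
        speed_out[idx] = np.minimum(speeds_now[tj], spd[idx])

    # steer away from the nearest wall within the clearance distance
    walls = getattr(arena, "walls", ())
    if walls:
        nw = len(walls)
        dists = np.empty((n, nw))
        away = np.empty((n, nw, 2))
        for w, seg in enumerate(walls):
            p1 = np.asarray(seg.p1)
            t = np.asarray(seg.p2) - p1
            L2 = float(t @ t)
            tau = np.clip(((pos - p1) @ t) / L2, 0.0, 1.0)
            closest = p1 + tau[:, None] * t
            dv = pos - closest
            d = np.hypot(dv[:, 0], dv[:, 1])
            dists[:, w] = d
            safe = np.where(d < 1e-12, 1.0, d)
            away[:, w] = dv / safe[:, None]
        wmin = np.argmin(dists, axis=1)
        dmin = dists[np.arange(n), wmin]
        close = dmin < config.wall_avoid_distance
        if np.any(close):
            wgt = 1.0 - dmin[close] / config.wall_avoid_distance
            adj = direction[close] + wgt[:, None] * away[close, wmin[close]]
            norm = np.hypot(adj[:, 0], adj[:, 1])
            ok = norm > 1e-12
            idx = np.nonzero(close)[0][ok]
            direction[idx] = adj[ok] / norm[ok, None]

    return direction * speed_out[:, None]


def desired_velocity(agent_index: int, positions, velocities, traits, arena,
                     config: BehaviorConfig) -> np.ndarray:
    """Desired velocity of one agent given everyone's state.

    ``traits`` is a sequence of :class:`AgentTraits` aligned with
    ``positions``/``velocities``.  Thin wrapper over the vectorized
    :func:`desired_velocities`.
    """
    spd = np.array([t.desired_speed for t in traits])
    rf = np.array([t.right_first for t in traits])
    return desired_velocities(positions, velocities, spd, rf, arena, config)[agent_index]
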