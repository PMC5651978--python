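"""Rectangular evacuation arena with a single exit flanked by guide walls.

Coordinates are global 2D Cartesian in meters with y increasing toward the
exit, which sits centered in the top wall (y = room length).  Two guide walls
of configurable length hinge at the exit-gap edges and are rotated by the
guide-wall angle theta (degrees) from the exit-wall plane into the room,
symmetric about the exit centerline; theta = 0 leaves a flat wall with a plain
opening and larger theta forms a funnel.  Agents start inside a waiting area
at the bottom of the room.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidGeometryError
from .geometry import WallSegment

__all__ = ["Arena", "build_arena"]


@dataclass(frozen=True)
class Arena:
    """Room geometry: outer walls, guide walls, exit line and waiting area."""

    width: float
    length: float
    exit_width: float
    guide_angle_deg: float
    guide_length: float
    waiting_depth: float
    walls: tuple[WallSegment, ...]
    exit_p1: tuple[float, float]
    exit_p2: tuple[float, float]

    @property
    def exit_target(self) -> np.ndarray:
        """Midpoint of the exit gap (the rushing-to-the-exit aim point)."""
        return 0.5 * (np.asarray(self.exit_p1) + np.asarray(self.exit_p2))

    def walls_array(self) -> np.ndarray:
        """Walls packed as (n, 6): e1x, e1y, e2x, e2y, nx, ny (kernel layout)."""
        out = np.empty((len(self.walls), 6))
        for i, w in enumerate(self.walls):
            out[i] = (*w.p1, *w.p2, *w.inward_normal)
        return out


def build_arena(
    theta_deg: float,
    *,
    room_width: float = 0.4,
    room_length: float = 0.6,
    exit_width: float = 0.06,
    guide_length: float = 0.15,
    waiting_depth: float = 0.25,
) -> Arena:
    """Construct the guide-wall arena for angle ``theta_deg`` in [0, 90).

    The guide walls rotate about the gap edges from the exit-wall plane toward
    the room interior.  Raises :class:`InvalidGeometryError` for angles outside
    [0, 90), non-positive dimensions, or guide walls that would leave the room.
    """
    if not (0.0 <= theta_deg < 90.0):
        raise InvalidGeometryError("guide-wall angle must lie in [0, 90) degrees")
    for name, v in (
        ("room_width", room_width),
        ("room_length", room_length),
        ("exit_width", exit_width),
        ("guide_length", guide_length),
        ("waiting_depth", waiting_depth),
    ):
        if v <= 0.0:
            raise InvalidGeometryError(f"{name} must be positive")
    if exit_width >= room_width:
        raise InvalidGeometryError("exit must be narrower than the room")

    w, length = room_width, room_length
    xgl = (w - exit_width) / 2.0
    xgr = xgl + exit_width
    th = math.radians(theta_deg)
    gdx = guide_length * math.cos(th)
    gdy = guide_length * math.sin(th)
    if xgl - gdx < 0.0 or length - gdy < 0.0:
        raise InvalidGeometryError("guide walls extend outside the room")

    inside = (w / 2.0, length / 2.0)
    walls = [
        WallSegment.from_endpoints((0.0, 0.0), (w, 0.0), inside),
        WallSegment.from_endpoints((0.0, 0.0), (0.0, length), inside),
        WallSegment.from_endpoints((w, 0.0), (w, length), inside),
    ]
    if theta_deg == 0.0:
        # guide walls are collinear with the exit wall: shorten the top wall
        # so the segments tile the plane without double-counting contacts
        walls.append(
            WallSegment.from_endpoints((0.0, length), (xgl - gdx, length), inside)
        )
        walls.append(
            WallSegment.from_endpoints((xgr + gdx, length), (w, length), inside)
        )
    else:
        walls.append(WallSegment.from_endpoints((0.0, length), (xgl, length), inside))
        walls.append(WallSegment.from_endpoints((xgr, length), (w, length), inside))
    walls.append(
        WallSegment.from_endpoints((xgl, length), (xgl - gdx, length - gdy), inside)
    )
    walls.append(
        WallSegment.from_endpoints((xgr, length), (xgr + gdx, length - gdy), inside)
    )

    return Arena(
        width=w,
        length=length,
        exit_width=exit_width,
        guide_angle_deg=theta_deg,
        guide_length=guide_length,
        waiting_depth=waiting_depth,
        walls=tuple(walls),
        exit_p1=(xgl, length),
        exit_p2=(xgr, length),
    )
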