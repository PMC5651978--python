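"""Elliptical agent footprints and their contacts with each other and walls.

Agents are soft 2D ellipses (semi-major ``a`` along the body axis, semi-minor
``b``).  A contact is summarized by a penetration depth ``delta``, a unit
normal pointing from the other body toward the subject body, and a contact
point inside the overlap region.  ``delta`` is defined as the width of the
overlap lens measured along the mid-normal of the chord joining the two
boundary crossings; in the circle limit this reduces to ``2 r - d`` exactly.

:func:`overlap_oracle` recomputes the same quantity by brute force (dense
boundary sampling plus bisection) and serves as an independent cross-check of
the quartic-based kernel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import _kernels
from .errors import DegenerateContactError, InvalidGeometryError

__all__ = [
    "EllipseShape",
    "WallSegment",
    "ContactInfo",
    "ellipse_overlap",
    "segment_contact",
    "overlap_oracle",
    "support_radius",
]


@dataclass(frozen=True)
class EllipseShape:
    """An elliptical footprint: center (m), orientation of the major axis
    relative to the global x-axis (rad, normalized to [0, pi)), and semi-axes
    ``a >= b > 0`` (m)."""

    center: tuple[float, float]
    orientation: float
    a: float
    b: float

    def __post_init__(self):
        if not (self.a >= self.b > 0.0):
            raise InvalidGeometryError(
                f"ellipse semi-axes must satisfy a >= b > 0, got a={self.a}, b={self.b}"
            )
        phi = float(self.orientation) % math.pi
        object.__setattr__(self, "orientation", phi)
        object.__setattr__(
            self, "center", (float(self.center[0]), float(self.center[1]))
        )

    def implicit(self, points: np.ndarray) -> np.ndarray:
        """Evaluate the implicit function (x'/a)^2 + (y'/b)^2 - 1 at ``points``
        (..., 2); negative inside, zero on the boundary."""
        p = np.asarray(points, dtype=float)
        qx = p[..., 0] - self.center[0]
        qy = p[..., 1] - self.center[1]
        c, s = math.cos(self.orientation), math.sin(self.orientation)
        xl = (qx * c + qy * s) / self.a
        yl = (-qx * s + qy * c) / self.b
        return xl * xl + yl * yl - 1.0

    def boundary(self, t: np.ndarray) -> np.ndarray:
        """Boundary points at parameter angles ``t`` (shape (..., 2))."""
        t = np.asarray(t, dtype=float)
        c, s = math.cos(self.orientation), math.sin(self.orientation)
        x = self.a * np.cos(t)
        y = self.b * np.sin(t)
        return np.stack(
            (self.center[0] + x * c - y * s, self.center[1] + x * s + y * c), axis=-1
        )


@dataclass(frozen=True)
class WallSegment:
    """A straight wall between two endpoints with a unit inward normal."""

    p1: tuple[float, float]
    p2: tuple[float, float]
    inward_normal: tuple[float, float]

    def __post_init__(self):
        p1 = np.asarray(self.p1, dtype=float)
        p2 = np.asarray(self.p2, dtype=float)
        t = p2 - p1
        length = float(np.hypot(*t))
        if length < 1e-12:
            raise InvalidGeometryError("wall segment endpoints coincide")
        n = np.asarray(self.inward_normal, dtype=float)
        nn = float(np.hypot(*n))
        if abs(nn - 1.0) > 1e-9:
            raise InvalidGeometryError("inward_normal must be a unit vector")
        if abs(float(np.dot(t, n))) > 1e-9 * length:
            raise InvalidGeometryError("inward_normal must be perpendicular to segment")
        object.__setattr__(self, "p1", (float(p1[0]), float(p1[1])))
        object.__setattr__(self, "p2", (float(p2[0]), float(p2[1])))
        object.__setattr__(self, "inward_normal", (float(n[0]), float(n[1])))

    @classmethod
    def from_endpoints(cls, p1, p2, interior_point) -> "WallSegment":
        """Build a segment whose inward normal faces ``interior_point``."""
        p1 = np.asarray(p1, dtype=float)
        p2 = np.asarray(p2, dtype=float)
        t = p2 - p1
        length = float(np.hypot(*t))
        if length < 1e-12:
            raise InvalidGeometryError("wall segment endpoints coincide")
        n = np.array([-t[1], t[0]]) / length
        if float(np.dot(np.asarray(interior_point, dtype=float) - p1, n)) < 0.0:
            n = -n
        return cls(tuple(p1), tuple(p2), (float(n[0]), float(n[1])))


@dataclass(frozen=True)
class ContactInfo:
    """Overlap depth (m), unit normal from the other body toward the subject
    body, and a contact point inside the overlap region."""

    overlap: float
    normal: tuple[float, float]
    point: tuple[float, float]


def _as_contact(status, delta, nx, ny, px, py) -> ContactInfo | None:
    if status == 2:
        raise DegenerateContactError("coincident bodies: contact normal undefined")
    if status == 0:
        return None
    return ContactInfo(float(delta), (float(nx), float(ny)), (float(px), float(py)))


def ellipse_overlap(shape_i: EllipseShape, shape_j: EllipseShape) -> ContactInfo | None:
    """Contact between two ellipses, or ``None`` when the boundaries do not
    intersect.  The normal points from ``shape_j`` toward ``shape_i``; swapping
    the arguments flips the normal and preserves ``delta``.

    Raises
    ------
    DegenerateContactError
        If the centers coincide (normal undefined).
    """
    return _as_contact(
        *_kernels.ellipse_pair_contact(
            shape_i.center[0], shape_i.center[1], shape_i.orientation,
            shape_i.a, shape_i.b,
            shape_j.center[0], shape_j.center[1], shape_j.orientation,
            shape_j.a, shape_j.b,
        )
    )


def segment_contact(shape: EllipseShape, wall: WallSegment) -> ContactInfo | None:
    """Penetration of an ellipse past a wall segment (treated as a thin
    two-sided barrier), or ``None``.  ``delta`` is the maximal penetration of
    the ellipse past the wall line; the normal pushes the agent back to the
    side its center is on.  Beyond the segment extent the near endpoint acts
    as a point obstacle with a center-to-corner normal."""
    return _as_contact(
        *_kernels.segment_contact(
            shape.center[0], shape.center[1], shape.orientation, shape.a, shape.b,
            wall.p1[0], wall.p1[1], wall.p2[0], wall.p2[1],
            wall.inward_normal[0], wall.inward_normal[1],
        )
    )


def support_radius(shape: EllipseShape, direction) -> float:
    """Distance from the center to the boundary along a unit ``direction``."""
    u = np.asarray(direction, dtype=float)
    return float(
        _kernels._support_radius(
            shape.a, shape.b,
            math.cos(shape.orientation), math.sin(shape.orientation),
            u[0], u[1],
        )
    )


# ---------------------------------------------------------------------------
# brute-force oracle


def _bisect(f, lo, hi, iters=80):
    flo = f(lo)
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        fm = f(mid)
        if flo * fm <= 0.0:
            hi = mid
        else:
            lo = mid
            flo = fm
    return 0.5 * (lo + hi)


def _boundary_crossings(shape_i: EllipseShape, shape_j: EllipseShape, n_samples: int):
    """Parameter angles where shape_i's boundary crosses shape_j's boundary,
    located by dense sampling and bisection."""
    t = np.linspace(0.0, 2.0 * math.pi, n_samples, endpoint=False)
    f = shape_j.implicit(shape_i.boundary(t))

    def g(tt):
        return float(shape_j.implicit(shape_i.boundary(np.array([tt])))[0])

    crossings = []
    for k in range(n_samples):
        k2 = (k + 1) % n_samples
        if f[k] == 0.0:
            crossings.append(t[k])
        elif f[k] * f[k2] < 0.0:
            hi = t[k2] if k2 != 0 else 2.0 * math.pi
            crossings.append(_bisect(g, t[k], hi))
    return crossings


def _ray_radius(shape: EllipseShape, direction, upper) -> float:
    """Boundary distance along ``direction`` from the center, by bisection on
    the implicit function (independent of the closed-form support radius)."""
    c = np.asarray(shape.center)
    u = np.asarray(direction, dtype=float)

    def g(r):
        return float(shape.implicit((c + r * u)[None, :])[0])

    return _bisect(g, 0.0, upper)


def overlap_oracle(
    shape_i: EllipseShape, shape_j: EllipseShape, n_samples: int = 4096
) -> float | None:
    """Brute-force penetration depth by dense boundary sampling.

    Computes the same lens-width-along-mid-normal quantity as
    :func:`ellipse_overlap` but with sampling + bisection only, so it is an
    independent check of the quartic-based kernel.  Returns ``None`` when the
    shapes do not overlap.
    """
    ci = np.asarray(shape_i.center)
    cj = np.asarray(shape_j.center)
    crossings = _boundary_crossings(shape_i, shape_j, n_samples)
    if len(crossings) >= 2:
        pts = shape_i.boundary(np.asarray(crossings))
        # most separated pair of crossings defines the chord
        best, pair = -1.0, (0, 1)
        for u in range(len(pts) - 1):
            for v in range(u + 1, len(pts)):
                sep = float(np.sum((pts[u] - pts[v]) ** 2))
                if sep > best:
                    best, pair = sep, (u, v)
        if best > 0.0:
            p1, p2 = pts[pair[0]], pts[pair[1]]
            mid = 0.5 * (p1 + p2)
            chord = (p2 - p1) / math.sqrt(best)
            n0 = np.array([-chord[1], chord[0]])
            span = 2.0 * max(shape_i.a, shape_j.a)

            def interval(shape):
                def g(s):
                    return float(shape.implicit((mid + s * n0)[None, :])[0])

                if g(0.0) > 0.0:
                    return None
                return (_bisect(g, 0.0, -span), _bisect(g, 0.0, span))

            ii = interval(shape_i)
            ij = interval(shape_j)
            if ii is not None and ij is not None:
                lo = max(min(ii), min(ij))
                hi = min(max(ii), max(ij))
                if hi > lo:
                    return hi - lo
    # containment / deep overlap: measure along the center line
    inside = (
        float(shape_j.implicit(ci[None, :])[0]) < 0.0
        or float(shape_i.implicit(cj[None, :])[0]) < 0.0
    )
    if not inside:
        return None
    d = float(np.hypot(*(ci - cj)))
    if d < 1e-12:
        raise DegenerateContactError("coincident centers in oracle")
    u = (ci - cj) / d
    ri = _ray_radius(shape_i, -u, 2.0 * shape_i.a)
    rj = _ray_radius(shape_j, u, 2.0 * shape_j.a)
    delta = ri + rj - d
    return delta if delta > 0.0 else None
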