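"""Ellipse shapes, pair contacts, wall contacts, and the sampling oracle."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from evacdem.errors import DegenerateContactError, InvalidGeometryError
from evacdem.geometry import (
    ContactInfo,
    EllipseShape,
    WallSegment,
    ellipse_overlap,
    overlap_oracle,
    segment_contact,
    support_radius,
)


# ---------------------------------------------------------------- EllipseShape


def test_ellipse_requires_ordered_positive_axes():
    with pytest.raises(InvalidGeometryError):
        EllipseShape((0, 0), 0.0, 0.01, 0.02)
    with pytest.raises(InvalidGeometryError):
        EllipseShape((0, 0), 0.0, 0.01, 0.0)


def test_orientation_normalized_to_half_turn():
    e = EllipseShape((0, 0), math.pi + 0.3, 0.03, 0.015)
    assert abs(e.orientation - 0.3) < 1e-12


def test_boundary_points_satisfy_implicit_equation():
    e = EllipseShape((0.2, -0.1), 0.7, 0.03, 0.015)
    t = np.linspace(0, 2 * math.pi, 97)
    vals = e.implicit(e.boundary(t))
    assert np.max(np.abs(vals)) < 1e-12


def test_implicit_sign_convention():
    e = EllipseShape((0.0, 0.0), 0.0, 0.03, 0.015)
    assert e.implicit(np.array([[0.0, 0.0]]))[0] < 0.0
    assert e.implicit(np.array([[0.05, 0.0]]))[0] > 0.0


@given(
    phi=st.floats(0.0, math.pi, allow_nan=False),
    ux=st.floats(-1.0, 1.0),
    uy=st.floats(-1.0, 1.0),
)
def test_support_radius_reaches_the_boundary(phi, ux, uy):
    norm = math.hypot(ux, uy)
    if norm < 1e-6:
        return
    u = np.array([ux, uy]) / norm
    e = EllipseShape((0.1, 0.2), phi, 0.03, 0.015)
    r = support_radius(e, u)
    assert e.b - 1e-12 <= r <= e.a + 1e-12
    p = np.asarray(e.center) + r * u
    assert abs(e.implicit(p[None, :])[0]) < 1e-9


# ---------------------------------------------------------------- pair contact


def test_separated_circles_do_not_contact():
    a = EllipseShape((0.0, 0.0), 0.0, 0.015, 0.015)
    b = EllipseShape((0.05, 0.0), 0.0, 0.015, 0.015)
    assert ellipse_overlap(a, b) is None


def test_circle_overlap_equals_closed_form():
    r, d = 0.015, 0.025
    a = EllipseShape((0.0, 0.0), 0.0, r, r)
    b = EllipseShape((d, 0.0), 0.0, r, r)
    c = ellipse_overlap(a, b)
    assert c is not None
    assert c.overlap == pytest.approx(2 * r - d, abs=1e-12)
    # normal points from b toward a
    assert c.normal[0] == pytest.approx(-1.0, abs=1e-9)
    assert abs(c.normal[1]) < 1e-9


def test_swap_flips_normal_and_preserves_depth():
    a = EllipseShape((0.0, 0.0), 0.3, 0.03, 0.015)
    b = EllipseShape((0.02, 0.012), 1.2, 0.03, 0.015)
    cab = ellipse_overlap(a, b)
    cba = ellipse_overlap(b, a)
    assert cab is not None and cba is not None
    assert cab.overlap == pytest.approx(cba.overlap, rel=1e-9)
    assert cab.normal[0] == pytest.approx(-cba.normal[0], abs=1e-9)
    assert cab.normal[1] == pytest.approx(-cba.normal[1], abs=1e-9)


def test_coincident_centers_raise_degenerate():
    a = EllipseShape((0.0, 0.0), 0.0, 0.03, 0.015)
    b = EllipseShape((0.0, 0.0), 1.0, 0.03, 0.015)
    with pytest.raises(DegenerateContactError):
        ellipse_overlap(a, b)


def test_crossed_ellipses_at_half_body_distance():
    # identical ellipses, one rotated a quarter turn: at center distance 0.05
    # with a = 0.03, b = 0.015 the boundaries do NOT meet (gap ~ 0.005), and
    # both the kernel and the oracle must agree on that
    a = EllipseShape((0.0, 0.0), 0.0, 0.03, 0.015)
    b = EllipseShape((0.05, 0.0), math.pi / 2, 0.03, 0.015)
    assert ellipse_overlap(a, b) is None
    assert overlap_oracle(a, b) is None
    # moved into genuine overlap the two agree numerically
    b2 = EllipseShape((0.04, 0.0), math.pi / 2, 0.03, 0.015)
    c = ellipse_overlap(a, b2)
    o = overlap_oracle(a, b2)
    assert c is not None and o is not None
    assert c.overlap == pytest.approx(o, abs=1e-6)


def test_contact_point_lies_inside_both_bodies():
    a = EllipseShape((0.0, 0.0), 0.2, 0.03, 0.015)
    b = EllipseShape((0.025, 0.01), 1.0, 0.03, 0.015)
    c = ellipse_overlap(a, b)
    assert c is not None
    p = np.asarray(c.point)[None, :]
    assert a.implicit(p)[0] <= 1e-9
    assert b.implicit(p)[0] <= 1e-9


def test_normal_is_unit_length():
    a = EllipseShape((0.0, 0.0), 0.4, 0.03, 0.015)
    b = EllipseShape((0.02, 0.015), 2.0, 0.03, 0.015)
    c = ellipse_overlap(a, b)
    assert c is not None
    assert math.hypot(*c.normal) == pytest.approx(1.0, abs=1e-12)


def _random_pair(rng):
    """A random nearby ellipse pair at mouse scale."""
    a1 = rng.uniform(0.015, 0.04)
    b1 = rng.uniform(0.008, a1)
    a2 = rng.uniform(0.015, 0.04)
    b2 = rng.uniform(0.008, a2)
    d = rng.uniform(0.0, 1.1) * (a1 + a2)
    ang = rng.uniform(0, 2 * math.pi)
    s1 = EllipseShape((0.0, 0.0), rng.uniform(0, math.pi), a1, b1)
    s2 = EllipseShape(
        (d * math.cos(ang), d * math.sin(ang)), rng.uniform(0, math.pi), a2, b2
    )
    return s1, s2


def test_kernel_agrees_with_oracle_on_random_pairs(rng):
    disagree_class = 0
    worst = 0.0
    checked = 0
    for _ in range(120):
        s1, s2 = _random_pair(rng)
        d = math.hypot(
            s1.center[0] - s2.center[0], s1.center[1] - s2.center[1]
        )
        if d < 1e-6:
            continue
        c = ellipse_overlap(s1, s2)
        o = overlap_oracle(s1, s2, n_samples=2048)
        if (c is None) != (o is None):
            # classification may differ only for grazing contacts
            depth = c.overlap if c is not None else o
            assert depth < 1e-6
            disagree_class += 1
            continue
        if c is not None:
            worst = max(worst, abs(c.overlap - o))
            checked += 1
    assert checked >= 30
    assert disagree_class <= 3
    assert worst < 1e-6


# ---------------------------------------------------------------- wall contact


def _floor():
    return WallSegment((0.0, 0.0), (1.0, 0.0), (0.0, 1.0))


def test_wall_normal_must_be_unit_and_perpendicular():
    with pytest.raises(InvalidGeometryError):
        WallSegment((0, 0), (1, 0), (0.0, 2.0))
    with pytest.raises(InvalidGeometryError):
        WallSegment((0, 0), (1, 0), (1.0, 0.0))
    with pytest.raises(InvalidGeometryError):
        WallSegment((0, 0), (0, 0), (0.0, 1.0))


def test_from_endpoints_orients_normal_toward_interior():
    w = WallSegment.from_endpoints((0, 0), (1, 0), (0.5, 3.0))
    assert w.inward_normal == pytest.approx((0.0, 1.0))
    w2 = WallSegment.from_endpoints((0, 0), (1, 0), (0.5, -3.0))
    assert w2.inward_normal == pytest.approx((0.0, -1.0))


def test_clear_ellipse_has_no_wall_contact():
    e = EllipseShape((0.5, 0.1), math.pi / 2, 0.03, 0.015)
    assert segment_contact(e, _floor()) is None


def test_wall_penetration_depth_circle_case():
    r, h = 0.015, 0.010
    e = EllipseShape((0.5, h), 0.0, r, r)
    c = segment_contact(e, _floor())
    assert c is not None
    assert c.overlap == pytest.approx(r - h, abs=1e-9)
    assert c.normal == pytest.approx((0.0, 1.0), abs=1e-9)


def test_wall_penetration_depth_aligned_ellipse():
    # minor axis perpendicular to the wall: depth = b - h
    e = EllipseShape((0.5, 0.010), 0.0, 0.03, 0.015)
    c = segment_contact(e, _floor())
    assert c is not None
    assert c.overlap == pytest.approx(0.015 - 0.010, abs=1e-9)


def test_wall_is_two_sided():
    below = EllipseShape((0.5, -0.010), 0.0, 0.015, 0.015)
    c = segment_contact(below, _floor())
    assert c is not None
    assert c.normal == pytest.approx((0.0, -1.0), abs=1e-9)


def test_endpoint_acts_as_point_obstacle():
    # center beyond the segment end: the corner pushes radially
    e = EllipseShape((1.01, 0.0), 0.0, 0.015, 0.015)
    c = segment_contact(e, _floor())
    assert c is not None
    assert c.normal[0] > 0.99
    assert c.overlap == pytest.approx(0.015 - 0.01, abs=1e-9)


def test_far_past_endpoint_is_clear():
    e = EllipseShape((1.2, 0.0), 0.0, 0.015, 0.015)
    assert segment_contact(e, _floor()) is None


@given(
    h=st.floats(0.001, 0.0149),
    phi=st.floats(0.0, math.pi),
)
def test_wall_depth_matches_sampled_lowest_point(h, phi):
    # the penetration equals how far the lowest boundary point dips below the
    # wall line, which dense sampling recovers independently of the kernel
    e = EllipseShape((0.5, h), phi, 0.03, 0.015)
    lowest = float(np.min(e.boundary(np.linspace(0, 2 * math.pi, 20001))[:, 1]))
    c = segment_contact(e, _floor())
    if lowest >= -1e-9:
        assert c is None or c.overlap < 1e-6
    else:
        assert c is not None
        assert c.overlap == pytest.approx(-lowest, abs=1e-6)


def test_contact_info_fields_are_plain_tuples():
    c = ContactInfo(0.001, (0.0, 1.0), (0.5, 0.0))
    assert isinstance(c.normal, tuple) and isinstance(c.point, tuple)
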