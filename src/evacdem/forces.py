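"""Contact and psychological forces acting on an agent.

Contacts follow a linear spring--dashpot in the normal direction,
``F_n = (k delta - eta (v_rel . n)) n``, with the dashpot coefficient derived
from the coefficient of restitution, plus a Coulomb-capped tangential spring
accumulated over the contact's lifetime (Cundall--Strack closure).

The psychological force relaxes the current velocity toward the desired
velocity over the response time ``dt_res``:

    F_psy = (m / dt_res) (v* - v0) = c (v* - v0)

so a free agent obeys ``v(t) = v* + (v0 - v*) exp(-t / dt_res)``.  The gain
``c`` is always derived from the agent's mass.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .geometry import ContactInfo

__all__ = [
    "ContactParams",
    "PsychParams",
    "ContactForce",
    "contact_force",
    "damping_coefficient",
    "psychological_force",
    "psychological_force_rotated",
    "measure_restitution",
    "simulate_relaxation",
    "fit_time_constant",
]


@dataclass(frozen=True)
class ContactParams:
    """Spring--dashpot contact parameters.

    Defaults are the mouse-model simulation parameters: normal and tangential
    spring constants 5.0e4 N/m, coefficient of restitution 0.1 and friction
    coefficient 0.1.
    """

    k_normal: float = 5.0e4
    k_tangential: float = 5.0e4
    restitution: float = 0.1
    friction: float = 0.1

    def __post_init__(self):
        if self.k_normal <= 0.0:
            raise ValueError("k_normal must be positive")
        if not (0.0 < self.restitution <= 1.0):
            raise ValueError("restitution must lie in (0, 1]")
        if self.friction < 0.0 or self.k_tangential < 0.0:
            raise ValueError("friction and k_tangential must be non-negative")

    def damping(self, m_eff: float) -> float:
        """Dashpot coefficient reproducing ``restitution`` for effective mass
        ``m_eff`` (see :func:`damping_coefficient`)."""
        return damping_coefficient(self.restitution, m_eff, self.k_normal)


@dataclass(frozen=True)
class PsychParams:
    """Response time (s) and derived gain ``c = mass / response_time`` (kg/s)."""

    mass: float = 0.030
    response_time: float = 0.1

    def __post_init__(self):
        if self.response_time <= 0.0 or self.mass <= 0.0:
            raise ValueError("mass and response_time must be positive")

    @property
    def gain(self) -> float:
        return self.mass / self.response_time


@dataclass(frozen=True)
class ContactForce:
    """Total contact force on the subject body plus its normal/tangential
    split and the updated tangential spring stretch (contact history)."""

    force: np.ndarray
    normal: np.ndarray
    tangential: np.ndarray
    stretch: np.ndarray


def damping_coefficient(e: float, m_eff: float, k: float) -> float:
    """Linear-dashpot coefficient eta (N s/m) that makes a binary
    spring--dashpot contact rebound with restitution ``e``:

        eta = 2 (-ln e) sqrt(m_eff k) / sqrt(pi^2 + ln^2 e)

    ``e = 1`` gives the elastic limit eta = 0; ``e = 0`` is unreachable for a
    linear dashpot and raises.
    """
    if not (0.0 < e <= 1.0):
        raise ValueError("restitution must lie in (0, 1]; a linear dashpot "
                         "cannot realize e = 0")
    if m_eff <= 0.0 or k <= 0.0:
        raise ValueError("m_eff and k must be positive")
    if e == 1.0:
        return 0.0
    ln_e = math.log(e)
    return 2.0 * (-ln_e) * math.sqrt(m_eff * k) / math.sqrt(math.pi**2 + ln_e**2)


def contact_force(
    contact: ContactInfo,
    v_rel,
    params: ContactParams,
    m_eff: float,
    stretch=None,
    dt: float = 0.0,
) -> ContactForce:
    """Contact force on the subject body (the one the normal points toward).

    ``v_rel`` is subject velocity minus other-body velocity.  The tangential
    spring stretch from the previous step is passed in ``stretch`` (2-vector)
    and advanced by ``v_t * dt``; its force is capped at ``friction * |F_n|``
    with slip resetting the stretch to the cap (Cundall--Strack).

    Raises ``ValueError`` if the contact has non-positive overlap.
    """
    if contact.overlap <= 0.0:
        raise ValueError("contact_force requires positive overlap")
    n = np.asarray(contact.normal, dtype=float)
    v = np.asarray(v_rel, dtype=float)
    eta = params.damping(m_eff)
    vn = float(v @ n)
    fn = params.k_normal * contact.overlap - eta * vn
    f_normal = fn * n
    xi = np.zeros(2) if stretch is None else np.asarray(stretch, dtype=float).copy()
    xi += (v - vn * n) * dt
    xi -= (xi @ n) * n
    f_t = -params.k_tangential * xi
    ft = float(np.hypot(*f_t))
    cap = params.friction * abs(fn)
    if ft > cap:
        f_t *= cap / ft if ft > 0.0 else 0.0
        if params.k_tangential > 0.0:
            xi = -f_t / params.k_tangential
    return ContactForce(f_normal + f_t, f_normal, f_t, xi)


def psychological_force(v_current, v_desired, mass: float, response_time: float):
    """Global-frame psychological force ``(m / dt_res) (v* - v0)``."""
    if response_time <= 0.0:
        raise ValueError("response_time must be positive")
    v0 = np.asarray(v_current, dtype=float)
    vs = np.asarray(v_desired, dtype=float)
    return (mass / response_time) * (vs - v0)


def psychological_force_rotated(v_current, v_desired, mass: float, response_time: float):
    """Psychological force evaluated in the desired-direction frame.

    The frame is rotated so the desired velocity has no x-bar component; the
    component formulas

        F_x = c [ (v*_xb - v0_xb) sin(th) + (v*_yb - v0_yb) cos(th) ]
        F_y = c [ -(v*_xb - v0_xb) cos(th) + (v*_yb - v0_yb) sin(th) ]

    with th the angle of the desired velocity compose to the same global
    vector as :func:`psychological_force`; this form exists for that
    equivalence check.
    """
    if response_time <= 0.0:
        raise ValueError("response_time must be positive")
    v0 = np.asarray(v_current, dtype=float)
    vs = np.asarray(v_desired, dtype=float)
    c = mass / response_time
    speed = float(np.hypot(*vs))
    if speed == 0.0:
        return -c * v0
    th = math.atan2(vs[1], vs[0])
    sth, cth = math.sin(th), math.cos(th)
    # global -> rotated frame (inverse of the frame composition)
    v0_xb = v0[0] * sth - v0[1] * cth
    v0_yb = v0[0] * cth + v0[1] * sth
    vs_xb = 0.0
    vs_yb = speed
    fx = c * ((vs_xb - v0_xb) * sth + (vs_yb - v0_yb) * cth)
    fy = c * (-(vs_xb - v0_xb) * cth + (vs_yb - v0_yb) * sth)
    return np.array([fx, fy])


# ---------------------------------------------------------------------------
# calibration / verification helpers


def measure_restitution(
    mass: float = 0.030,
    k: float = 5.0e4,
    restitution: float = 0.1,
    radius: float = 0.015,
    speed: float = 0.1,
    dt: float = 1e-5,
    friction: float = 0.0,
) -> float:
    """Measured post/pre relative-normal-speed ratio of a simulated head-on
    binary collision (psychological force off).

    Two identical circular agents approach at +-``speed`` along x and are
    integrated with semi-implicit Euler through the full contact; the ratio of
    separation to approach speed is the realized coefficient of restitution,
    which should match ``restitution`` because the dashpot is derived from it.
    """
    from .geometry import EllipseShape, ellipse_overlap

    params = ContactParams(
        k_normal=k, k_tangential=k, restitution=restitution, friction=friction
    )
    m_eff = mass / 2.0
    eta = params.damping(m_eff)
    gap = 1e-4
    x1, x2 = -radius - gap / 2.0, radius + gap / 2.0
    v1, v2 = speed, -speed
    v_pre = v1 - v2
    t_max = 1.0
    touched = False
    steps = int(round(t_max / dt))
    for _ in range(steps):
        s1 = EllipseShape((x1, 0.0), 0.0, radius, radius)
        s2 = EllipseShape((x2, 0.0), 0.0, radius, radius)
        c = ellipse_overlap(s1, s2)
        f1 = 0.0
        if c is not None:
            touched = True
            vn = (v1 - v2) * c.normal[0]
            fn = k * c.overlap - eta * vn
            f1 = fn * c.normal[0]
        v1 += f1 / mass * dt
        v2 += -f1 / mass * dt
        x1 += v1 * dt
        x2 += v2 * dt
        if touched and c is None and v2 - v1 > 0.0:
            break
    return abs(v2 - v1) / v_pre


def simulate_relaxation(
    mass: float = 0.030,
    response_time: float = 0.1,
    desired_speed: float = 0.4,
    dt: float = 1e-3,
    t_end: float = 1.0,
):
    """Speed trace of an isolated agent starting from rest under the
    psychological force alone (semi-implicit Euler).  Returns ``(t, v)``
    arrays with the sample at the end of each step."""
    n = int(round(t_end / dt))
    v = np.zeros(n)
    vs = desired_speed
    cur = 0.0
    for i in range(n):
        f = psychological_force((cur, 0.0), (vs, 0.0), mass, response_time)[0]
        cur += f / mass * dt
        v[i] = cur
    t = dt * np.arange(1, n + 1)
    return t, v


def fit_time_constant(t, v, v_star: float) -> float:
    """Exponential time constant tau fitted to ``v(t) = v*(1 - exp(-t/tau))``
    by linear regression of ``log(1 - v/v*)`` on ``t`` (points within 1% of
    saturation are excluded)."""
    t = np.asarray(t, dtype=float)
    v = np.asarray(v, dtype=float)
    resid = 1.0 - v / v_star
    mask = resid > 1e-2
    if mask.sum() < 2:
        raise ValueError("not enough unsaturated samples to fit a time constant")
    slope = np.polyfit(t[mask], np.log(resid[mask]), 1)[0]
    return -1.0 / slope
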