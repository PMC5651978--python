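"""Compiled numerical kernels (numba) for contact detection and time stepping.

The public modules (:mod:`evacdem.geometry`, :mod:`evacdem.simulator`) wrap these
functions; nothing here validates input.  All kernels are pure float64 math so a
fixed seed reproduces bit-identical trajectories.

Contact status codes returned by the pair/segment kernels:

* ``0`` — no contact
* ``1`` — contact; ``(delta, nx, ny, px, py)`` are valid
* ``2`` — degenerate (coincident centers; normal undefined)
"""

import math

import numpy as np
from numba import njit

_IMAG_TOL = 1e-10
_LEAD_TOL = 1e-12


@njit(cache=True)
def _support_radius(a, b, cphi, sphi, ux, uy):
    """Distance from the ellipse center to its boundary along unit direction u."""
    cl = ux * cphi + uy * sphi
    sl = -ux * sphi + uy * cphi
    return a * b / math.sqrt(b * b * cl * cl + a * a * sl * sl)


@njit(cache=True)
def _line_ellipse_interval(mx, my, nx, ny, cx, cy, phi, a, b):
    """Intersect the line M + s*n with an ellipse; return (ok, s_lo, s_hi)."""
    cp = math.cos(phi)
    sp = math.sin(phi)
    qx = mx - cx
    qy = my - cy
    mxl = (qx * cp + qy * sp) / a
    myl = (-qx * sp + qy * cp) / b
    dxl = (nx * cp + ny * sp) / a
    dyl = (-nx * sp + ny * cp) / b
    A = dxl * dxl + dyl * dyl
    B = 2.0 * (mxl * dxl + myl * dyl)
    C = mxl * mxl + myl * myl - 1.0
    disc = B * B - 4.0 * A * C
    if disc <= 0.0 or A == 0.0:
        return False, 0.0, 0.0
    sq = math.sqrt(disc)
    return True, (-B - sq) / (2.0 * A), (-B + sq) / (2.0 * A)


@njit(cache=True)
def _poly_real_roots(coeffs, out):
    """Real roots of a polynomial (descending coeffs) via companion eigenvalues.

    Writes roots into ``out`` and returns their count.  Leading coefficients
    that are negligible relative to the largest one are trimmed.
    """
    n = coeffs.shape[0]
    scale = 0.0
    for i in range(n):
        v = abs(coeffs[i])
        if v > scale:
            scale = v
    if scale == 0.0:
        return 0
    lead = 0
    while lead < n - 1 and abs(coeffs[lead]) < _LEAD_TOL * scale:
        lead += 1
    deg = n - 1 - lead
    if deg < 1:
        return 0
    c0 = coeffs[lead]
    # complex dtype: numba's eigvals rejects real input with complex spectrum
    comp = np.zeros((deg, deg), dtype=np.complex128)
    for i in range(deg):
        comp[0, i] = -coeffs[lead + 1 + i] / c0
    for i in range(1, deg):
        comp[i, i - 1] = 1.0
    eig = np.linalg.eigvals(comp)
    cnt = 0
    for i in range(deg):
        re = eig[i].real
        im = eig[i].imag
        mag = abs(re) + abs(im)
        if abs(im) <= 1e-7 * (1.0 + mag):
            out[cnt] = re
            cnt += 1
    return cnt


@njit(cache=True)
def ellipse_pair_contact(cix, ciy, phii, ai, bi, cjx, cjy, phij, aj, bj):
    """Overlap of two ellipses.

    Parametrizes ellipse *i*'s boundary, finds its crossings with ellipse *j*'s
    boundary through the quartic in tan(t/2), and measures the overlap lens
    width along the chord mid-normal.  The normal points from *j* toward *i*.

    Returns ``(status, delta, nx, ny, px, py)``.
    """
    dx = cix - cjx
    dy = ciy - cjy
    d2 = dx * dx + dy * dy
    rsum = ai + aj
    if d2 > rsum * rsum:
        return 0, 0.0, 0.0, 0.0, 0.0, 0.0
    if d2 < 1e-24:
        # coincident centers: the push-apart direction is undefined
        return 2, 0.0, 0.0, 0.0, 0.0, 0.0

    cpi = math.cos(phii)
    spi = math.sin(phii)
    # p_i(t) = c_i + cos(t) * U + sin(t) * W
    Ux = ai * cpi
    Uy = ai * spi
    Wx = -bi * spi
    Wy = bi * cpi
    cpj = math.cos(phij)
    spj = math.sin(phij)
    # components of f_j(p_i(t)) = A c^2 + B s c + C s^2 + D c + E s + F0
    a0 = (dx * cpj + dy * spj) / aj
    ac = (Ux * cpj + Uy * spj) / aj
    as_ = (Wx * cpj + Wy * spj) / aj
    b0 = (-dx * spj + dy * cpj) / bj
    bc = (-Ux * spj + Uy * cpj) / bj
    bs = (-Wx * spj + Wy * cpj) / bj
    A = ac * ac + bc * bc
    C = as_ * as_ + bs * bs
    B = 2.0 * (ac * as_ + bc * bs)
    D = 2.0 * (a0 * ac + b0 * bc)
    E = 2.0 * (a0 * as_ + b0 * bs)
    F0 = a0 * a0 + b0 * b0 - 1.0

    # quartic in u = tan(t/2)
    coeffs = np.empty(5)
    coeffs[0] = A - D + F0
    coeffs[1] = 2.0 * (E - B)
    coeffs[2] = 2.0 * F0 - 2.0 * A + 4.0 * C
    coeffs[3] = 2.0 * (B + E)
    coeffs[4] = A + D + F0

    roots = np.empty(4)
    nroots = _poly_real_roots(coeffs, roots)

    ts = np.empty(5)
    nts = 0
    for r in range(nroots):
        ts[nts] = 2.0 * math.atan(roots[r])
        nts += 1
    # t = pi corresponds to u -> inf (vanishing quartic leading coefficient)
    cscale = max(abs(A), abs(C), abs(F0), 1e-30)
    if abs(coeffs[0]) < 1e-9 * cscale:
        ts[nts] = math.pi
        nts += 1

    # Newton-polish on g(t) and collect distinct boundary points
    px_ = np.empty(5)
    py_ = np.empty(5)
    npts = 0
    for r in range(nts):
        t = ts[r]
        for _ in range(3):
            c = math.cos(t)
            s = math.sin(t)
            g = A * c * c + B * s * c + C * s * s + D * c + E * s + F0
            dg = (
                -2.0 * A * c * s
                + B * (c * c - s * s)
                + 2.0 * C * s * c
                - D * s
                + E * c
            )
            if dg != 0.0:
                t -= g / dg
        c = math.cos(t)
        s = math.sin(t)
        g = A * c * c + B * s * c + C * s * s + D * c + E * s + F0
        if abs(g) > 1e-6:
            continue
        x = cix + c * Ux + s * Wx
        y = ciy + c * Uy + s * Wy
        dup = False
        for k in range(npts):
            if abs(px_[k] - x) < 1e-9 * ai and abs(py_[k] - y) < 1e-9 * ai:
                dup = True
                break
        if not dup:
            px_[npts] = x
            py_[npts] = y
            npts += 1

    if npts >= 2:
        # chord: the most separated pair of crossings
        best = -1.0
        i1 = 0
        i2 = 1
        for u in range(npts - 1):
            for v in range(u + 1, npts):
                sep = (px_[u] - px_[v]) ** 2 + (py_[u] - py_[v]) ** 2
                if sep > best:
                    best = sep
                    i1 = u
                    i2 = v
        if best > 0.0:
            mx = 0.5 * (px_[i1] + px_[i2])
            my = 0.5 * (py_[i1] + py_[i2])
            chx = px_[i2] - px_[i1]
            chy = py_[i2] - py_[i1]
            clen = math.sqrt(best)
            n0x = -chy / clen
            n0y = chx / clen
            oki, silo, sihi = _line_ellipse_interval(
                mx, my, n0x, n0y, cix, ciy, phii, ai, bi
            )
            okj, sjlo, sjhi = _line_ellipse_interval(
                mx, my, n0x, n0y, cjx, cjy, phij, aj, bj
            )
            if oki and okj:
                lo = max(silo, sjlo)
                hi = min(sihi, sjhi)
                delta = hi - lo
                if delta <= 0.0:
                    return 0, 0.0, 0.0, 0.0, 0.0, 0.0
                smid = 0.5 * (lo + hi)
                pcx = mx + smid * n0x
                pcy = my + smid * n0y
                if n0x * dx + n0y * dy < 0.0:
                    n0x = -n0x
                    n0y = -n0y
                return 1, delta, n0x, n0y, pcx, pcy

    # no usable chord: deep overlap (center containment) or separation
    inside_i_in_j = F0 < 0.0  # f_j at c_i is exactly F0
    qx = (-dx * cpi - dy * spi) / ai
    qy = (dx * spi - dy * cpi) / bi
    inside_j_in_i = qx * qx + qy * qy - 1.0 < 0.0
    if not (inside_i_in_j or inside_j_in_i):
        return 0, 0.0, 0.0, 0.0, 0.0, 0.0
    d = math.sqrt(d2)
    if d < 1e-12:
        return 2, 0.0, 0.0, 0.0, 0.0, 0.0
    nux = dx / d
    nuy = dy / d
    ri = _support_radius(ai, bi, cpi, spi, -nux, -nuy)
    rj = _support_radius(aj, bj, cpj, spj, nux, nuy)
    delta = ri + rj - d
    if delta <= 0.0:
        return 0, 0.0, 0.0, 0.0, 0.0, 0.0
    bix = cix - nux * ri
    biy = ciy - nuy * ri
    bjx = cjx + nux * rj
    bjy = cjy + nuy * rj
    return 1, delta, nux, nuy, 0.5 * (bix + bjx), 0.5 * (biy + bjy)


@njit(cache=True)
def segment_contact(cx, cy, phi, a, b, e1x, e1y, e2x, e2y, nwx, nwy):
    """Penetration of an ellipse past a wall segment (two-sided thin wall).

    The normal returned points from the wall toward the agent.  If the deepest
    point projects outside the segment extent the near endpoint is treated as a
    point obstacle with a center-to-corner normal.

    Returns ``(status, delta, nx, ny, px, py)``.
    """
    dsx = cx - e1x
    dsy = cy - e1y
    d_signed = dsx * nwx + dsy * nwy
    sgn = 1.0 if d_signed >= 0.0 else -1.0
    nx = nwx * sgn
    ny = nwy * sgn
    d = d_signed * sgn
    cp = math.cos(phi)
    sp = math.sin(phi)
    n1 = nx * cp + ny * sp
    n2 = -nx * sp + ny * cp
    h = math.sqrt(a * a * n1 * n1 + b * b * n2 * n2)
    delta = h - d
    if delta <= 0.0:
        return 0, 0.0, 0.0, 0.0, 0.0, 0.0
    # deepest boundary point against the wall line
    mnx = a * a * n1 * cp - b * b * n2 * sp
    mny = a * a * n1 * sp + b * b * n2 * cp
    xdx = cx - mnx / h
    xdy = cy - mny / h
    tx = e2x - e1x
    ty = e2y - e1y
    L2 = tx * tx + ty * ty
    tau = ((xdx - e1x) * tx + (xdy - e1y) * ty) / L2
    if 0.0 <= tau <= 1.0:
        return 1, delta, nx, ny, xdx + 0.5 * delta * nx, xdy + 0.5 * delta * ny
    # corner contact with the nearer endpoint
    ex = e1x if tau < 0.0 else e2x
    ey = e1y if tau < 0.0 else e2y
    qx = cx - ex
    qy = cy - ey
    dist = math.sqrt(qx * qx + qy * qy)
    if dist < 1e-14:
        return 2, 0.0, 0.0, 0.0, 0.0, 0.0
    ux = qx / dist
    uy = qy / dist
    r = _support_radius(a, b, cp, sp, ux, uy)
    dc = r - dist
    if dc <= 0.0:
        return 0, 0.0, 0.0, 0.0, 0.0, 0.0
    return 1, dc, ux, uy, ex, ey


@njit(cache=True)
def advance(
    pos,
    vel,
    phi,
    active,
    exit_time,
    a,
    b,
    mass,
    gain,
    des_vel,
    walls,
    gap_x0,
    gap_x1,
    exit_y,
    has_exit,
    k_n,
    k_t,
    mu,
    eta_pair,
    eta_wall,
    pair_stretch,
    wall_stretch,
    t0,
    dt,
    n_sub,
    rot_tau,
):
    """Advance all active agents by one decision step ``dt``.

    Physics (contacts + psychological force) integrates on ``n_sub`` sub-steps
    with semi-implicit Euler; the desired velocities ``des_vel`` are held fixed
    over the step.  Tangential (Coulomb-capped spring) contact history lives in
    ``pair_stretch``/``wall_stretch`` and is reset whenever a contact breaks.
    Agents whose center crosses the exit line inside the gap are deactivated
    with a linearly interpolated ``exit_time``.

    Body orientation relaxes toward the direction of motion with time constant
    ``rot_tau`` (seconds); an instantaneous snap would rotate the major axis
    into neighbouring bodies within one sub-step, conjuring deep overlaps whose
    spring energy is injected from nowhere.

    Returns the index of the first agent with non-finite state, or -1.
    """
    n = pos.shape[0]
    nw = walls.shape[0]
    h = dt / n_sub
    rot_frac = 1.0 - math.exp(-h / rot_tau) if rot_tau > 0.0 else 1.0
    broad2 = (2.0 * a) * (2.0 * a)
    F = np.zeros((n, 2))
    for s in range(n_sub):
        for i in range(n):
            if active[i]:
                F[i, 0] = gain * (des_vel[i, 0] - vel[i, 0])
                F[i, 1] = gain * (des_vel[i, 1] - vel[i, 1])
            else:
                F[i, 0] = 0.0
                F[i, 1] = 0.0
        # agent-agent contacts
        for i in range(n - 1):
            if not active[i]:
                continue
            for j in range(i + 1, n):
                if not active[j]:
                    continue
                ddx = pos[i, 0] - pos[j, 0]
                ddy = pos[i, 1] - pos[j, 1]
                if ddx * ddx + ddy * ddy > broad2:
                    pair_stretch[i, j, 0] = 0.0
                    pair_stretch[i, j, 1] = 0.0
                    continue
                st, delta, nx, ny, _, _ = ellipse_pair_contact(
                    pos[i, 0], pos[i, 1], phi[i], a, b,
                    pos[j, 0], pos[j, 1], phi[j], a, b,
                )
                if st != 1:
                    pair_stretch[i, j, 0] = 0.0
                    pair_stretch[i, j, 1] = 0.0
                    continue
                vrx = vel[i, 0] - vel[j, 0]
                vry = vel[i, 1] - vel[j, 1]
                vn = vrx * nx + vry * ny
                fn = k_n * delta - eta_pair * vn
                xx = pair_stretch[i, j, 0] + (vrx - vn * nx) * h
                xy = pair_stretch[i, j, 1] + (vry - vn * ny) * h
                xn = xx * nx + xy * ny
                xx -= xn * nx
                xy -= xn * ny
                ftx = -k_t * xx
                fty = -k_t * xy
                ft = math.sqrt(ftx * ftx + fty * fty)
                fcap = mu * abs(fn)
                if ft > fcap:
                    sc = fcap / ft if ft > 0.0 else 0.0
                    ftx *= sc
                    fty *= sc
                    if k_t > 0.0:
                        xx = -ftx / k_t
                        xy = -fty / k_t
                pair_stretch[i, j, 0] = xx
                pair_stretch[i, j, 1] = xy
                fx = fn * nx + ftx
                fy = fn * ny + fty
                F[i, 0] += fx
                F[i, 1] += fy
                F[j, 0] -= fx
                F[j, 1] -= fy
        # agent-wall contacts
        for i in range(n):
            if not active[i]:
                continue
            for w in range(nw):
                st, delta, nx, ny, _, _ = segment_contact(
                    pos[i, 0], pos[i, 1], phi[i], a, b,
                    walls[w, 0], walls[w, 1], walls[w, 2], walls[w, 3],
                    walls[w, 4], walls[w, 5],
                )
                if st != 1:
                    wall_stretch[i, w, 0] = 0.0
                    wall_stretch[i, w, 1] = 0.0
                    continue
                vn = vel[i, 0] * nx + vel[i, 1] * ny
                fn = k_n * delta - eta_wall * vn
                xx = wall_stretch[i, w, 0] + (vel[i, 0] - vn * nx) * h
                xy = wall_stretch[i, w, 1] + (vel[i, 1] - vn * ny) * h
                xn = xx * nx + xy * ny
                xx -= xn * nx
                xy -= xn * ny
                ftx = -k_t * xx
                fty = -k_t * xy
                ft = math.sqrt(ftx * ftx + fty * fty)
                fcap = mu * abs(fn)
                if ft > fcap:
                    sc = fcap / ft if ft > 0.0 else 0.0
                    ftx *= sc
                    fty *= sc
                    if k_t > 0.0:
                        xx = -ftx / k_t
                        xy = -fty / k_t
                wall_stretch[i, w, 0] = xx
                wall_stretch[i, w, 1] = xy
                F[i, 0] += fn * nx + ftx
                F[i, 1] += fn * ny + fty
        # semi-implicit Euler update + exit detection
        for i in range(n):
            if not active[i]:
                continue
            vel[i, 0] += F[i, 0] / mass * h
            vel[i, 1] += F[i, 1] / mass * h
            newx = pos[i, 0] + vel[i, 0] * h
            newy = pos[i, 1] + vel[i, 1] * h
            if not (math.isfinite(newx) and math.isfinite(newy)):
                return i
            if has_exit and pos[i, 1] <= exit_y < newy:
                fr = (exit_y - pos[i, 1]) / (newy - pos[i, 1])
                xc = pos[i, 0] + (newx - pos[i, 0]) * fr
                if gap_x0 <= xc <= gap_x1:
                    exit_time[i] = t0 + s * h + fr * h
                    active[i] = False
                    pos[i, 0] = xc
                    pos[i, 1] = exit_y
                    vel[i, 0] = 0.0
                    vel[i, 1] = 0.0
                    continue
            pos[i, 0] = newx
            pos[i, 1] = newy
            sp2 = vel[i, 0] * vel[i, 0] + vel[i, 1] * vel[i, 1]
            if sp2 > 1e-12:
                ang = math.atan2(vel[i, 1], vel[i, 0])
                if ang < 0.0:
                    ang += math.pi
                if ang >= math.pi:
                    ang -= math.pi
                # shortest pi-periodic difference, relaxed over rot_tau
                diff = ang - phi[i]
                if diff > 0.5 * math.pi:
                    diff -= math.pi
                elif diff < -0.5 * math.pi:
                    diff += math.pi
                newphi = phi[i] + rot_frac * diff
                if newphi < 0.0:
                    newphi += math.pi
                elif newphi >= math.pi:
                    newphi -= math.pi
                phi[i] = newphi
    return -1
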