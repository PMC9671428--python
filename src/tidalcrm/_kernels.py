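"""Numba-compiled primitive distance queries and the stepping contact detector.

Every device component is an *inflated primitive*: a core shape (point, segment
or triangle) plus an inflation radius.  The signed clearance between the seal
capsule (core segment, radius ``seal_r``) and a component is then

    clearance = dist(core_seal, core_component) - seal_r - inflation

which is exact, smooth through contact and negative exactly when the two solids
overlap.  The rotor rotates about the +X axis through the hub centre; rotation
about X preserves x-coordinates, so rotating components are handled by rotating
the *seal* endpoints into the rotor frame (two points instead of many).

Prim-kind codes used throughout: 0 = triangle, 1 = sphere, 2 = capsule segment.
"""

import math

import numpy as np
from numba import njit

BIG = 1.0e30


# ---------------------------------------------------------------------------
# scalar primitive queries (Ericson, Real-Time Collision Detection)
# ---------------------------------------------------------------------------

@njit(cache=False)
def _point_seg(px, py, pz, ax, ay, az, bx, by, bz):
    """Closest point on segment AB to P.  Returns (dist2, qx, qy, qz)."""
    abx = bx - ax
    aby = by - ay
    abz = bz - az
    t_num = (px - ax) * abx + (py - ay) * aby + (pz - az) * abz
    denom = abx * abx + aby * aby + abz * abz
    if denom <= 0.0:
        t = 0.0
    else:
        t = t_num / denom
        if t < 0.0:
            t = 0.0
        elif t > 1.0:
            t = 1.0
    qx = ax + t * abx
    qy = ay + t * aby
    qz = az + t * abz
    dx = px - qx
    dy = py - qy
    dz = pz - qz
    return dx * dx + dy * dy + dz * dz, qx, qy, qz


@njit(cache=False)
def _seg_seg(p1x, p1y, p1z, q1x, q1y, q1z, p2x, p2y, p2z, q2x, q2y, q2z):
    """Closest points between segments P1Q1 and P2Q2.

    Returns (dist2, c1x, c1y, c1z, c2x, c2y, c2z).
    """
    d1x = q1x - p1x
    d1y = q1y - p1y
    d1z = q1z - p1z
    d2x = q2x - p2x
    d2y = q2y - p2y
    d2z = q2z - p2z
    rx = p1x - p2x
    ry = p1y - p2y
    rz = p1z - p2z
    a = d1x * d1x + d1y * d1y + d1z * d1z
    e = d2x * d2x + d2y * d2y + d2z * d2z
    f = d2x * rx + d2y * ry + d2z * rz
    eps = 1.0e-14
    if a <= eps and e <= eps:
        s = 0.0
        t = 0.0
    elif a <= eps:
        s = 0.0
        t = f / e
        t = min(max(t, 0.0), 1.0)
    else:
        c = d1x * rx + d1y * ry + d1z * rz
        if e <= eps:
            t = 0.0
            s = min(max(-c / a, 0.0), 1.0)
        else:
            b = d1x * d2x + d1y * d2y + d1z * d2z
            denom = a * e - b * b
            if denom > eps:
                s = min(max((b * f - c * e) / denom, 0.0), 1.0)
            else:
                s = 0.0
            t = (b * s + f) / e
            if t < 0.0:
                t = 0.0
                s = min(max(-c / a, 0.0), 1.0)
            elif t > 1.0:
                t = 1.0
                s = min(max((b - c) / a, 0.0), 1.0)
    c1x = p1x + s * d1x
    c1y = p1y + s * d1y
    c1z = p1z + s * d1z
    c2x = p2x + t * d2x
    c2y = p2y + t * d2y
    c2z = p2z + t * d2z
    dx = c1x - c2x
    dy = c1y - c2y
    dz = c1z - c2z
    return dx * dx + dy * dy + dz * dz, c1x, c1y, c1z, c2x, c2y, c2z


@njit(cache=False)
def _point_tri(px, py, pz, ax, ay, az, bx, by, bz, cx, cy, cz):
    """Closest point on triangle ABC to P.  Returns (dist2, qx, qy, qz)."""
    abx = bx - ax
    aby = by - ay
    abz = bz - az
    acx = cx - ax
    acy = cy - ay
    acz = cz - az
    apx = px - ax
    apy = py - ay
    apz = pz - az
    d1 = abx * apx + aby * apy + abz * apz
    d2 = acx * apx + acy * apy + acz * apz
    if d1 <= 0.0 and d2 <= 0.0:
        qx, qy, qz = ax, ay, az
    else:
        bpx = px - bx
        bpy = py - by
        bpz = pz - bz
        d3 = abx * bpx + aby * bpy + abz * bpz
        d4 = acx * bpx + acy * bpy + acz * bpz
        if d3 >= 0.0 and d4 <= d3:
            qx, qy, qz = bx, by, bz
        else:
            vc = d1 * d4 - d3 * d2
            if vc <= 0.0 and d1 >= 0.0 and d3 <= 0.0:
                v = d1 / (d1 - d3) if d1 != d3 else 0.0
                qx = ax + v * abx
                qy = ay + v * aby
                qz = az + v * abz
            else:
                cpx = px - cx
                cpy = py - cy
                cpz = pz - cz
                d5 = abx * cpx + aby * cpy + abz * cpz
                d6 = acx * cpx + acy * cpy + acz * cpz
                if d6 >= 0.0 and d5 <= d6:
                    qx, qy, qz = cx, cy, cz
                else:
                    vb = d5 * d2 - d1 * d6
                    if vb <= 0.0 and d2 >= 0.0 and d6 <= 0.0:
                        w = d2 / (d2 - d6) if d2 != d6 else 0.0
                        qx = ax + w * acx
                        qy = ay + w * acy
                        qz = az + w * acz
                    else:
                        va = d3 * d6 - d5 * d4
                        if va <= 0.0 and (d4 - d3) >= 0.0 and (d5 - d6) >= 0.0:
                            w = (d4 - d3) / ((d4 - d3) + (d5 - d6))
                            qx = bx + w * (cx - bx)
                            qy = by + w * (cy - by)
                            qz = bz + w * (cz - bz)
                        else:
                            denom = va + vb + vc
                            if denom != 0.0:
                                v = vb / denom
                                w = vc / denom
                            else:
                                v = 0.0
                                w = 0.0
                            qx = ax + abx * v + acx * w
                            qy = ay + aby * v + acy * w
                            qz = az + abz * v + acz * w
    dx = px - qx
    dy = py - qy
    dz = pz - qz
    return dx * dx + dy * dy + dz * dz, qx, qy, qz


@njit(cache=False)
def _seg_tri(px, py, pz, qx, qy, qz, ax, ay, az, bx, by, bz, cx, cy, cz):
    """Closest points between segment PQ and triangle ABC.

    Returns (dist2, sx, sy, sz, tx, ty, tz) with S on the segment and T on the
    triangle.  dist2 == 0 when the segment crosses the triangle's interior.
    """
    # plane-crossing test
    nx = (by - ay) * (cz - az) - (bz - az) * (cy - ay)
    ny = (bz - az) * (cx - ax) - (bx - ax) * (cz - az)
    nz = (bx - ax) * (cy - ay) - (by - ay) * (cx - ax)
    n2 = nx * nx + ny * ny + nz * nz
    if n2 > 1.0e-20:
        dp = nx * (px - ax) + ny * (py - ay) + nz * (pz - az)
        dq = nx * (qx - ax) + ny * (qy - ay) + nz * (qz - az)
        if dp * dq < 0.0:
            u = dp / (dp - dq)
            ix = px + u * (qx - px)
            iy = py + u * (qy - py)
            iz = pz + u * (qz - pz)
            # barycentric inside-test of the intersection point
            v0x = bx - ax
            v0y = by - ay
            v0z = bz - az
            v1x = cx - ax
            v1y = cy - ay
            v1z = cz - az
            v2x = ix - ax
            v2y = iy - ay
            v2z = iz - az
            d00 = v0x * v0x + v0y * v0y + v0z * v0z
            d01 = v0x * v1x + v0y * v1y + v0z * v1z
            d11 = v1x * v1x + v1y * v1y + v1z * v1z
            d20 = v2x * v0x + v2y * v0y + v2z * v0z
            d21 = v2x * v1x + v2y * v1y + v2z * v1z
            denom = d00 * d11 - d01 * d01
            if denom != 0.0:
                v = (d11 * d20 - d01 * d21) / denom
                w = (d00 * d21 - d01 * d20) / denom
                if v >= 0.0 and w >= 0.0 and v + w <= 1.0:
                    return 0.0, ix, iy, iz, ix, iy, iz
    best = BIG
    bsx = bsy = bsz = btx = bty = btz = 0.0
    # segment endpoints vs triangle
    d2, tx, ty, tz = _point_tri(px, py, pz, ax, ay, az, bx, by, bz, cx, cy, cz)
    if d2 < best:
        best = d2
        bsx, bsy, bsz, btx, bty, btz = px, py, pz, tx, ty, tz
    d2, tx, ty, tz = _point_tri(qx, qy, qz, ax, ay, az, bx, by, bz, cx, cy, cz)
    if d2 < best:
        best = d2
        bsx, bsy, bsz, btx, bty, btz = qx, qy, qz, tx, ty, tz
    # segment vs the three edges
    d2, s1, s2, s3, t1, t2, t3 = _seg_seg(px, py, pz, qx, qy, qz, ax, ay, az, bx, by, bz)
    if d2 < best:
        best = d2
        bsx, bsy, bsz, btx, bty, btz = s1, s2, s3, t1, t2, t3
    d2, s1, s2, s3, t1, t2, t3 = _seg_seg(px, py, pz, qx, qy, qz, bx, by, bz, cx, cy, cz)
    if d2 < best:
        best = d2
        bsx, bsy, bsz, btx, bty, btz = s1, s2, s3, t1, t2, t3
    d2, s1, s2, s3, t1, t2, t3 = _seg_seg(px, py, pz, qx, qy, qz, cx, cy, cz, ax, ay, az)
    if d2 < best:
        best = d2
        bsx, bsy, bsz, btx, bty, btz = s1, s2, s3, t1, t2, t3
    return best, bsx, bsy, bsz, btx, bty, btz


@njit(cache=False)
def _wrap_pi(a):
    """Wrap angle to (-pi, pi]."""
    twopi = 2.0 * math.pi
    a = a % twopi
    if a > math.pi:
        a -= twopi
    return a


# ---------------------------------------------------------------------------
# assembly-level clearance scans
# ---------------------------------------------------------------------------

@njit(cache=False)
def clearance_scan(p0x, p0y, p0z, p1x, p1y, p1z, seal_r, theta,
                   tri_v, tri_inf, tri_rot,
                   sph_c, sph_r, sph_rot,
                   seg_a, seg_b, seg_r, seg_rot,
                   hub_y, hub_z):
    """Minimum signed clearance over every component, arbitrary seal pose.

    Returns (clearance, kind, index).  kind is -1 when the device is empty.
    """
    ct = math.cos(-theta)
    st = math.sin(-theta)
    # seal endpoints in the rotor frame (rotation about +X through the hub)
    r0y = hub_y + ct * (p0y - hub_y) - st * (p0z - hub_z)
    r0z = hub_z + st * (p0y - hub_y) + ct * (p0z - hub_z)
    r1y = hub_y + ct * (p1y - hub_y) - st * (p1z - hub_z)
    r1z = hub_z + st * (p1y - hub_y) + ct * (p1z - hub_z)
    best = BIG
    bkind = -1
    bidx = -1
    for i in range(tri_v.shape[0]):
        if tri_rot[i]:
            ay0, az0, by0, bz0 = r0y, r0z, r1y, r1z
        else:
            ay0, az0, by0, bz0 = p0y, p0z, p1y, p1z
        d2 = _seg_tri(p0x, ay0, az0, p1x, by0, bz0,
                      tri_v[i, 0, 0], tri_v[i, 0, 1], tri_v[i, 0, 2],
                      tri_v[i, 1, 0], tri_v[i, 1, 1], tri_v[i, 1, 2],
                      tri_v[i, 2, 0], tri_v[i, 2, 1], tri_v[i, 2, 2])[0]
        c = math.sqrt(d2) - seal_r - tri_inf[i]
        if c < best:
            best = c
            bkind = 0
            bidx = i
    for i in range(sph_c.shape[0]):
        if sph_rot[i]:
            ay0, az0, by0, bz0 = r0y, r0z, r1y, r1z
        else:
            ay0, az0, by0, bz0 = p0y, p0z, p1y, p1z
        d2 = _point_seg(sph_c[i, 0], sph_c[i, 1], sph_c[i, 2],
                        p0x, ay0, az0, p1x, by0, bz0)[0]
        c = math.sqrt(d2) - seal_r - sph_r[i]
        if c < best:
            best = c
            bkind = 1
            bidx = i
    for i in range(seg_a.shape[0]):
        if seg_rot[i]:
            ay0, az0, by0, bz0 = r0y, r0z, r1y, r1z
        else:
            ay0, az0, by0, bz0 = p0y, p0z, p1y, p1z
        d2 = _seg_seg(p0x, ay0, az0, p1x, by0, bz0,
                      seg_a[i, 0], seg_a[i, 1], seg_a[i, 2],
                      seg_b[i, 0], seg_b[i, 1], seg_b[i, 2])[0]
        c = math.sqrt(d2) - seal_r - seg_r[i]
        if c < best:
            best = c
            bkind = 2
            bidx = i
    return best, bkind, bidx


@njit(cache=False)
def clearance_points(p0x, p0y, p0z, p1x, p1y, p1z, seal_r, theta, kind, idx,
                     tri_v, tri_inf, tri_rot,
                     sph_c, sph_r, sph_rot,
                     seg_a, seg_b, seg_r, seg_rot,
                     hub_y, hub_z):
    """Realizing surface points for one component.

    Returns (clearance, sx, sy, sz, dx, dy, dz): closest point on the seal
    surface and on the component surface (world frame).
    """
    rotating = False
    if kind == 0:
        rotating = tri_rot[idx] != 0
        inf = tri_inf[idx]
    elif kind == 1:
        rotating = sph_rot[idx] != 0
        inf = sph_r[idx]
    else:
        rotating = seg_rot[idx] != 0
        inf = seg_r[idx]
    if rotating:
        ct = math.cos(-theta)
        st = math.sin(-theta)
        a0y = hub_y + ct * (p0y - hub_y) - st * (p0z - hub_z)
        a0z = hub_z + st * (p0y - hub_y) + ct * (p0z - hub_z)
        a1y = hub_y + ct * (p1y - hub_y) - st * (p1z - hub_z)
        a1z = hub_z + st * (p1y - hub_y) + ct * (p1z - hub_z)
    else:
        a0y, a0z, a1y, a1z = p0y, p0z, p1y, p1z
    if kind == 0:
        d2, sx, sy, sz, tx, ty, tz = _seg_tri(
            p0x, a0y, a0z, p1x, a1y, a1z,
            tri_v[idx, 0, 0], tri_v[idx, 0, 1], tri_v[idx, 0, 2],
            tri_v[idx, 1, 0], tri_v[idx, 1, 1], tri_v[idx, 1, 2],
            tri_v[idx, 2, 0], tri_v[idx, 2, 1], tri_v[idx, 2, 2])
    elif kind == 1:
        # _point_seg returns the closest point on the *seal* core segment;
        # the device core point is the sphere centre itself
        d2, sx, sy, sz = _point_seg(sph_c[idx, 0], sph_c[idx, 1], sph_c[idx, 2],
                                    p0x, a0y, a0z, p1x, a1y, a1z)
        tx, ty, tz = sph_c[idx, 0], sph_c[idx, 1], sph_c[idx, 2]
    else:
        d2, sx, sy, sz, tx, ty, tz = _seg_seg(
            p0x, a0y, a0z, p1x, a1y, a1z,
            seg_a[idx, 0], seg_a[idx, 1], seg_a[idx, 2],
            seg_b[idx, 0], seg_b[idx, 1], seg_b[idx, 2])
    core = math.sqrt(d2)
    clear = core - seal_r - inf
    if rotating:
        # rotate realizing core points back to the world frame
        ct = math.cos(theta)
        st = math.sin(theta)
        ny = hub_y + ct * (sy - hub_y) - st * (sz - hub_z)
        nz = hub_z + st * (sy - hub_y) + ct * (sz - hub_z)
        sy, sz = ny, nz
        ny = hub_y + ct * (ty - hub_y) - st * (tz - hub_z)
        nz = hub_z + st * (ty - hub_y) + ct * (tz - hub_z)
        ty, tz = ny, nz
    ux = tx - sx
    uy = ty - sy
    uz = tz - sz
    if core > 1.0e-12:
        ux /= core
        uy /= core
        uz /= core
    else:
        ux = uy = uz = 0.0
    seal_sx = sx + seal_r * ux
    seal_sy = sy + seal_r * uy
    seal_sz = sz + seal_r * uz
    dev_sx = tx - inf * ux
    dev_sy = ty - inf * uy
    dev_sz = tz - inf * uz
    return clear, seal_sx, seal_sy, seal_sz, dev_sx, dev_sy, dev_sz


@njit(cache=False)
def _clearance_axial(t, y, z, alpha, x0, v, seal_half, seal_r, omega, phase,
                     tri_v, tri_inf, tri_rot, tri_ref, tri_halfang, tri_tlo, tri_thi,
                     sph_c, sph_r, sph_rot, sph_tlo, sph_thi,
                     seg_a, seg_b, seg_r, seg_rot, seg_tlo, seg_thi,
                     hub_y, hub_z):
    """Windowed/culled clearance for the axial-transit fast path.

    The seal core segment is parallel to +X at lateral position (y, z).  Time
    windows are conservative (clearance is certainly positive outside them), so
    skipping a component never changes the detected sign.
    """
    cx = x0 + v * t
    p0x = cx - seal_half
    p1x = cx + seal_half
    theta = phase + omega * t
    ct = math.cos(-theta)
    st = math.sin(-theta)
    yr = hub_y + ct * (y - hub_y) - st * (z - hub_z)
    zr = hub_z + st * (y - hub_y) + ct * (z - hub_z)
    best = BIG
    bkind = -1
    bidx = -1
    for i in range(tri_v.shape[0]):
        if t < tri_tlo[i] or t > tri_thi[i]:
            continue
        if tri_rot[i]:
            if tri_halfang[i] < math.pi:
                rel = _wrap_pi(alpha - theta - tri_ref[i])
                if abs(rel) > tri_halfang[i]:
                    continue
            yy, zz = yr, zr
        else:
            yy, zz = y, z
        d2 = _seg_tri(p0x, yy, zz, p1x, yy, zz,
                      tri_v[i, 0, 0], tri_v[i, 0, 1], tri_v[i, 0, 2],
                      tri_v[i, 1, 0], tri_v[i, 1, 1], tri_v[i, 1, 2],
                      tri_v[i, 2, 0], tri_v[i, 2, 1], tri_v[i, 2, 2])[0]
        c = math.sqrt(d2) - seal_r - tri_inf[i]
        if c < best:
            best = c
            bkind = 0
            bidx = i
    for i in range(sph_c.shape[0]):
        if t < sph_tlo[i] or t > sph_thi[i]:
            continue
        if sph_rot[i]:
            yy, zz = yr, zr
        else:
            yy, zz = y, z
        d2 = _point_seg(sph_c[i, 0], sph_c[i, 1], sph_c[i, 2],
                        p0x, yy, zz, p1x, yy, zz)[0]
        c = math.sqrt(d2) - seal_r - sph_r[i]
        if c < best:
            best = c
            bkind = 1
            bidx = i
    for i in range(seg_a.shape[0]):
        if t < seg_tlo[i] or t > seg_thi[i]:
            continue
        if seg_rot[i]:
            yy, zz = yr, zr
        else:
            yy, zz = y, z
        d2 = _seg_seg(p0x, yy, zz, p1x, yy, zz,
                      seg_a[i, 0], seg_a[i, 1], seg_a[i, 2],
                      seg_b[i, 0], seg_b[i, 1], seg_b[i, 2])[0]
        c = math.sqrt(d2) - seal_r - seg_r[i]
        if c < best:
            best = c
            bkind = 2
            bidx = i
    return best, bkind, bidx


@njit(cache=False)
def simulate_cell(y, z, alpha, x0, v, seal_half, seal_r,
                  phases, omega, dt, t_start, t_stop,
                  tri_v, tri_inf, tri_rot, tri_ref, tri_halfang, tri_tlo, tri_thi,
                  sph_c, sph_r, sph_rot, sph_tlo, sph_thi,
                  seg_a, seg_b, seg_r, seg_rot, seg_tlo, seg_thi,
                  hub_y, hub_z, contact_tol, time_tol,
                  out_hit, out_t, out_kind, out_idx, out_pts):
    """Run every initial rotor phase for one release point.

    First contact per phase is bracketed by bisection to |clearance| <=
    contact_tol (and time interval <= time_tol).  out_pts[k] receives
    (seal point xyz, device point xyz) at contact.
    """
    n = phases.shape[0]
    for k in range(n):
        phase = phases[k]
        out_hit[k] = 0
        out_t[k] = np.nan
        out_kind[k] = -1
        out_idx[k] = -1
        if t_start > t_stop:
            continue
        t_prev = t_start
        c_prev, _, _ = _clearance_axial(
            t_prev, y, z, alpha, x0, v, seal_half, seal_r, omega, phase,
            tri_v, tri_inf, tri_rot, tri_ref, tri_halfang, tri_tlo, tri_thi,
            sph_c, sph_r, sph_rot, sph_tlo, sph_thi,
            seg_a, seg_b, seg_r, seg_rot, seg_tlo, seg_thi, hub_y, hub_z)
        t = t_prev
        found = False
        t_hit = 0.0
        if c_prev <= 0.0:
            # window padding guarantees positive clearance at entry; degenerate
            # configurations (release inside the device) still report a contact
            found = True
            t_hit = t_prev
        while not found and t < t_stop:
            t = t_prev + dt
            if t > t_stop:
                t = t_stop
            c, _, _ = _clearance_axial(
                t, y, z, alpha, x0, v, seal_half, seal_r, omega, phase,
                tri_v, tri_inf, tri_rot, tri_ref, tri_halfang, tri_tlo, tri_thi,
                sph_c, sph_r, sph_rot, sph_tlo, sph_thi,
                seg_a, seg_b, seg_r, seg_rot, seg_tlo, seg_thi, hub_y, hub_z)
            if c <= 0.0:
                # bisection on the sign change in [t_prev, t]
                lo = t_prev
                hi = t
                c_hi = c
                t_hit = hi
                for _ in range(80):
                    if (hi - lo) <= time_tol and abs(c_hi) <= contact_tol:
                        break
                    mid = 0.5 * (lo + hi)
                    cm, _, _ = _clearance_axial(
                        mid, y, z, alpha, x0, v, seal_half, seal_r, omega, phase,
                        tri_v, tri_inf, tri_rot, tri_ref, tri_halfang,
                        tri_tlo, tri_thi,
                        sph_c, sph_r, sph_rot, sph_tlo, sph_thi,
                        seg_a, seg_b, seg_r, seg_rot, seg_tlo, seg_thi,
                        hub_y, hub_z)
                    if cm <= 0.0:
                        hi = mid
                        c_hi = cm
                    else:
                        lo = mid
                    if hi - lo < 1.0e-12:
                        break
                t_hit = hi
                found = True
                break
            t_prev = t
            c_prev = c
            if t >= t_stop:
                break
        if found:
            ch, kind, idx = _clearance_axial(
                t_hit, y, z, alpha, x0, v, seal_half, seal_r, omega, phase,
                tri_v, tri_inf, tri_rot, tri_ref, tri_halfang, tri_tlo, tri_thi,
                sph_c, sph_r, sph_rot, sph_tlo, sph_thi,
                seg_a, seg_b, seg_r, seg_rot, seg_tlo, seg_thi, hub_y, hub_z)
            cx = x0 + v * t_hit
            theta = phase + omega * t_hit
            cc, sx, sy, sz, dx, dy, dz = clearance_points(
                cx - seal_half, y, z, cx + seal_half, y, z, seal_r, theta,
                kind, idx,
                tri_v, tri_inf, tri_rot, sph_c, sph_r, sph_rot,
                seg_a, seg_b, seg_r, seg_rot, hub_y, hub_z)
            out_hit[k] = 1
            out_t[k] = t_hit
            out_kind[k] = kind
            out_idx[k] = idx
            out_pts[k, 0] = sx
            out_pts[k, 1] = sy
            out_pts[k, 2] = sz
            out_pts[k, 3] = dx
            out_pts[k, 4] = dy
            out_pts[k, 5] = dz


@njit(cache=False)
def brute_force_scan(y, z, x0, v, seal_half, seal_r, phase, omega,
                     dt, n_steps, pts, pts_r, pts_rot,
                     hub_y, hub_z, dev_xlo, dev_xhi):
    """Fixed-step dense point-sampled detector (oracle).

    Steps the configuration at fixed dt; at each step tests every sampled
    device core point (with its exact inflation radius) against the exact
    seal capsule.  Returns (collided, step_index) of the first step with
    clearance <= 0, or (False, -1).
    """
    m = pts.shape[0]
    for istep in range(n_steps):
        t = istep * dt
        cx = x0 + v * t
        if cx + seal_half + seal_r < dev_xlo or cx - seal_half - seal_r > dev_xhi:
            continue
        theta = phase + omega * t
        ct = math.cos(-theta)
        st = math.sin(-theta)
        yr = hub_y + ct * (y - hub_y) - st * (z - hub_z)
        zr = hub_z + st * (y - hub_y) + ct * (z - hub_z)
        p0 = cx - seal_half
        p1 = cx + seal_half
        for j in range(m):
            px = pts[j, 0]
            py = pts[j, 1]
            pz = pts[j, 2]
            if pts_rot[j]:
                sy0, sz0 = yr, zr
            else:
                sy0, sz0 = y, z
            # closest point on the seal core segment (along +X) to P
            qx = px
            if qx < p0:
                qx = p0
            elif qx > p1:
                qx = p1
            ddx = px - qx
            ddy = py - sy0
            ddz = pz - sz0
            rr = seal_r + pts_r[j]
            if ddx * ddx + ddy * ddy + ddz * ddz <= rr * rr:
                return True, istep
    return False, -1
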