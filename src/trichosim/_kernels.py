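"""Batched numba kernels for the simulation inner loop.

Positions are stored as one contiguous float64 array of shape
``(n_trichomes, n_vertices, 3)`` (all trichomes share the same segment count).
Every kernel here mirrors a reference implementation in
:mod:`trichosim.elasticity`, :mod:`trichosim.contact` or
:mod:`trichosim.dynamics`; the test suite asserts agreement between the two
routes.  Single-threaded on purpose: runs are reproducible and the target
problem sizes fit one core.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_NJIT = dict(cache=True, fastmath=False)
# The force kernels tolerate value-safe float reassociation; the constraint
# solver and pair builder stay strict (their tolerances define contracts).
_NJIT_FAST = dict(cache=True, fastmath={"contract", "reassoc", "nsz", "arcp"})


@njit(**_NJIT_FAST)
def batched_tangents(x):
    """Unit vertex tangents, head-to-tail orientation, for all trichomes."""
    n_tri, m, _ = x.shape
    t = np.empty_like(x)
    for f in range(n_tri):
        for i in range(m):
            lo = 0 if i == 0 else i - 1
            hi = m - 1 if i == m - 1 else i + 1
            dx = x[f, hi, 0] - x[f, lo, 0]
            dy = x[f, hi, 1] - x[f, lo, 1]
            dz = x[f, hi, 2] - x[f, lo, 2]
            inv = 1.0 / np.sqrt(dx * dx + dy * dy + dz * dz)
            t[f, i, 0] = dx * inv
            t[f, i, 1] = dy * inv
            t[f, i, 2] = dz * inv
    return t


@njit(**_NJIT_FAST)
def add_bending_forces(x, alpha, l, out):
    """Accumulate -grad of the bending energy into ``out``."""
    n_tri, m, _ = x.shape
    coeff = 2.0 * alpha / l
    for f in range(n_tri):
        for j in range(1, m - 1):
            ux = x[f, j, 0] - x[f, j - 1, 0]
            uy = x[f, j, 1] - x[f, j - 1, 1]
            uz = x[f, j, 2] - x[f, j - 1, 2]
            vx = x[f, j + 1, 0] - x[f, j, 0]
            vy = x[f, j + 1, 1] - x[f, j, 1]
            vz = x[f, j + 1, 2] - x[f, j, 2]
            nu = np.sqrt(ux * ux + uy * uy + uz * uz)
            nv = np.sqrt(vx * vx + vy * vy + vz * vz)
            dot = ux * vx + uy * vy + uz * vz
            denom = nu * nv + dot
            kx = 2.0 * (uy * vz - uz * vy) / denom
            ky = 2.0 * (uz * vx - ux * vz) / denom
            kz = 2.0 * (ux * vy - uy * vx) / denom
            kb2 = kx * kx + ky * ky + kz * kz
            # s = (nv/nu) u + v ; w = (nu/nv) v + u
            ru, rv = nv / nu, nu / nv
            sx, sy, sz = ru * ux + vx, ru * uy + vy, ru * uz + vz
            wx, wy, wz = rv * vx + ux, rv * vy + uy, rv * vz + uz
            # cross products v x kb and u x kb
            cvx = vy * kz - vz * ky
            cvy = vz * kx - vx * kz
            cvz = vx * ky - vy * kx
            cux = uy * kz - uz * ky
            cuy = uz * kx - ux * kz
            cuz = ux * ky - uy * kx
            gpx = (-2.0 * cvx + sx * kb2) / denom
            gpy = (-2.0 * cvy + sy * kb2) / denom
            gpz = (-2.0 * cvz + sz * kb2) / denom
            gnx = (-2.0 * cux - wx * kb2) / denom
            gny = (-2.0 * cuy - wy * kb2) / denom
            gnz = (-2.0 * cuz - wz * kb2) / denom
            out[f, j - 1, 0] -= coeff * gpx
            out[f, j - 1, 1] -= coeff * gpy
            out[f, j - 1, 2] -= coeff * gpz
            out[f, j + 1, 0] -= coeff * gnx
            out[f, j + 1, 1] -= coeff * gny
            out[f, j + 1, 2] -= coeff * gnz
            out[f, j, 0] += coeff * (gpx + gnx)
            out[f, j, 1] += coeff * (gpy + gny)
            out[f, j, 2] += coeff * (gpz + gnz)


@njit(**_NJIT_FAST)
def add_gliding_forces(tangents, polarity, zeta, v0, out):
    n_tri, m, _ = tangents.shape
    for f in range(n_tri):
        s = zeta * v0 * polarity[f]
        for i in range(m):
            out[f, i, 0] += s * tangents[f, i, 0]
            out[f, i, 1] += s * tangents[f, i, 1]
            out[f, i, 2] += s * tangents[f, i, 2]


@njit(**_NJIT_FAST)
def add_wall_forces(x, height, theta, wall_c, out):
    n_tri, m, _ = x.shape
    lo = 0.5 * theta
    hi = height - 0.5 * theta
    for f in range(n_tri):
        for i in range(m):
            z = x[f, i, 2]
            if z > hi:
                out[f, i, 2] += wall_c * (hi - z)
            elif z < lo:
                out[f, i, 2] += wall_c * (lo - z)


@njit(**_NJIT_FAST)
def project_velocities(forces, tangents, zeta, b_aniso):
    """Anisotropic overdamped mobility: v = (F_par + F_perp / b) / zeta."""
    n_tri, m, _ = forces.shape
    v = np.empty_like(forces)
    inv_zeta = 1.0 / zeta
    inv_b = 1.0 / b_aniso
    for f in range(n_tri):
        for i in range(m):
            fx = forces[f, i, 0]
            fy = forces[f, i, 1]
            fz = forces[f, i, 2]
            tx = tangents[f, i, 0]
            ty = tangents[f, i, 1]
            tz = tangents[f, i, 2]
            fpar = fx * tx + fy * ty + fz * tz
            v[f, i, 0] = inv_zeta * (fpar * tx + (fx - fpar * tx) * inv_b)
            v[f, i, 1] = inv_zeta * (fpar * ty + (fy - fpar * ty) * inv_b)
            v[f, i, 2] = inv_zeta * (fpar * tz + (fz - fpar * tz) * inv_b)
    return v


@njit(**_NJIT)
def constraint_project(x, l, rel_tol, max_iter):
    """Project all chains back onto equal edge lengths ``l`` (in place).

    Newton iterations; each solves the exact tridiagonal Lagrange system of
    the linearized constraints (Thomas algorithm), giving the minimal
    uniform-weighted correction per iteration.  Returns True when every bond
    is within ``rel_tol * l`` of ``l``.
    """
    n_tri, m, _ = x.shape
    nb = m - 1
    ux = np.empty(nb)
    uy = np.empty(nb)
    uz = np.empty(nb)
    c = np.empty(nb)
    diag = np.empty(nb)
    off = np.empty(nb)
    lam = np.empty(nb)
    ok = True
    for f in range(n_tri):
        converged = False
        for _ in range(max_iter):
            err = 0.0
            for k in range(nb):
                dx = x[f, k + 1, 0] - x[f, k, 0]
                dy = x[f, k + 1, 1] - x[f, k, 1]
                dz = x[f, k + 1, 2] - x[f, k, 2]
                ln = np.sqrt(dx * dx + dy * dy + dz * dz)
                ux[k] = dx / ln
                uy[k] = dy / ln
                uz[k] = dz / ln
                c[k] = ln - l
                e = abs(c[k]) / l
                if e > err:
                    err = e
            if err < rel_tol:
                converged = True
                break
            # tridiagonal system (B B^T) lam = c
            for k in range(nb):
                diag[k] = 2.0
            for k in range(nb - 1):
                off[k] = -(ux[k] * ux[k + 1] + uy[k] * uy[k + 1] + uz[k] * uz[k + 1])
            # Thomas forward sweep
            for k in range(1, nb):
                w = off[k - 1] / diag[k - 1]
                diag[k] -= w * off[k - 1]
                c[k] -= w * c[k - 1]
            lam[nb - 1] = c[nb - 1] / diag[nb - 1]
            for k in range(nb - 2, -1, -1):
                lam[k] = (c[k] - off[k] * lam[k + 1]) / diag[k]
            # apply correction  x_m += lam_m u_m - lam_{m-1} u_{m-1}
            for k in range(nb):
                x[f, k, 0] += lam[k] * ux[k]
                x[f, k, 1] += lam[k] * uy[k]
                x[f, k, 2] += lam[k] * uz[k]
                x[f, k + 1, 0] -= lam[k] * ux[k]
                x[f, k + 1, 1] -= lam[k] * uy[k]
                x[f, k + 1, 2] -= lam[k] * uz[k]
        if not converged:
            # final residual check after the last correction
            err = 0.0
            for k in range(nb):
                dx = x[f, k + 1, 0] - x[f, k, 0]
                dy = x[f, k + 1, 1] - x[f, k, 1]
                dz = x[f, k + 1, 2] - x[f, k, 2]
                ln = np.sqrt(dx * dx + dy * dy + dz * dz)
                e = abs(ln - l) / l
                if e > err:
                    err = e
            if err >= rel_tol:
                ok = False
    return ok


@njit(**_NJIT)
def _seg_seg_dist_sq(x1, x2, x3, x4):
    """Exact squared distance between two segments (closest-point clamping)."""
    d1x, d1y, d1z = x2[0] - x1[0], x2[1] - x1[1], x2[2] - x1[2]
    d2x, d2y, d2z = x4[0] - x3[0], x4[1] - x3[1], x4[2] - x3[2]
    rx, ry, rz = x1[0] - x3[0], x1[1] - x3[1], x1[2] - x3[2]
    a = d1x * d1x + d1y * d1y + d1z * d1z
    e = d2x * d2x + d2y * d2y + d2z * d2z
    f = d2x * rx + d2y * ry + d2z * rz
    c = d1x * rx + d1y * ry + d1z * rz
    b = d1x * d2x + d1y * d2y + d1z * d2z
    denom = a * e - b * b
    if denom > 1e-12 * a * e:
        s = (b * f - c * e) / denom
        s = 0.0 if s < 0.0 else (1.0 if s > 1.0 else s)
    else:
        s = 0.0
    t = (b * s + f) / e
    if t < 0.0:
        t = 0.0
        s = -c / a
    elif t > 1.0:
        t = 1.0
        s = (b - c) / a
    s = 0.0 if s < 0.0 else (1.0 if s > 1.0 else s)
    px = x1[0] + s * d1x - (x3[0] + t * d2x)
    py = x1[1] + s * d1y - (x3[1] + t * d2y)
    pz = x1[2] + s * d1z - (x3[2] + t * d2z)
    return px * px + py * py + pz * pz


@njit(**_NJIT)
def build_pairs(x, cutoff, width, depth, exclusion_window):
    """Spatial-hash candidate edge pairs (global ids, i < j).

    Edges are binned by their minimum-image midpoints on a 2D grid; midpoint
    candidates are refined by the exact segment-segment distance, keeping
    pairs closer than ``cutoff``.  Same-trichome pairs within
    ``exclusion_window`` edges are excluded.
    """
    n_tri, m, _ = x.shape
    ne = m - 1
    n_edges = n_tri * ne
    # longest edge, for the midpoint prefilter margin
    lmax = 0.0
    for f in range(n_tri):
        for e in range(ne):
            dx = x[f, e + 1, 0] - x[f, e, 0]
            dy = x[f, e + 1, 1] - x[f, e, 1]
            dz = x[f, e + 1, 2] - x[f, e, 2]
            d2 = dx * dx + dy * dy + dz * dz
            if d2 > lmax:
                lmax = d2
    cutoff_mid = cutoff + np.sqrt(lmax)
    mx = np.empty(n_edges)
    my = np.empty(n_edges)
    mz = np.empty(n_edges)
    for f in range(n_tri):
        for e in range(ne):
            g = f * ne + e
            px = 0.5 * (x[f, e, 0] + x[f, e + 1, 0])
            py = 0.5 * (x[f, e, 1] + x[f, e + 1, 1])
            mz[g] = 0.5 * (x[f, e, 2] + x[f, e + 1, 2])
            mx[g] = px - np.floor(px / width) * width
            my[g] = py - np.floor(py / depth) * depth
    ncx = max(1, int(width / cutoff_mid))
    ncy = max(1, int(depth / cutoff_mid))
    n_cells = ncx * ncy
    cell = np.empty(n_edges, dtype=np.int64)
    counts = np.zeros(n_cells + 1, dtype=np.int64)
    for g in range(n_edges):
        ix = int(mx[g] / width * ncx)
        iy = int(my[g] / depth * ncy)
        if ix >= ncx:
            ix = ncx - 1
        if iy >= ncy:
            iy = ncy - 1
        cell[g] = ix * ncy + iy
        counts[cell[g] + 1] += 1
    for k in range(1, n_cells + 1):
        counts[k] += counts[k - 1]
    order = np.empty(n_edges, dtype=np.int64)
    fill = counts[:-1].copy()
    for g in range(n_edges):
        order[fill[cell[g]]] = g
        fill[cell[g]] += 1

    cap = 16 * n_edges + 16
    pa = np.empty(cap, dtype=np.int64)
    pb = np.empty(cap, dtype=np.int64)
    count = 0
    cut2 = cutoff_mid * cutoff_mid
    neigh = np.empty(9, dtype=np.int64)
    for g1 in range(n_edges):
        ix = cell[g1] // ncy
        iy = cell[g1] % ncy
        nn = 0
        for dx_ in range(-1, 2):
            for dy_ in range(-1, 2):
                jx = (ix + dx_) % ncx
                jy = (iy + dy_) % ncy
                cid = jx * ncy + jy
                dup = False
                for q in range(nn):
                    if neigh[q] == cid:
                        dup = True
                        break
                if not dup:
                    neigh[nn] = cid
                    nn += 1
        for q in range(nn):
            cid = neigh[q]
            for idx in range(counts[cid], counts[cid + 1]):
                g2 = order[idx]
                if g2 <= g1:
                    continue
                f1, e1 = g1 // ne, g1 % ne
                f2, e2 = g2 // ne, g2 % ne
                if f1 == f2 and abs(e1 - e2) <= exclusion_window:
                    continue
                ddx = mx[g2] - mx[g1]
                ddy = my[g2] - my[g1]
                ddx -= np.round(ddx / width) * width
                ddy -= np.round(ddy / depth) * depth
                ddz = mz[g2] - mz[g1]
                if ddx * ddx + ddy * ddy + ddz * ddz >= cut2:
                    continue
                # exact refinement: minimum-image shift edge 2 next to edge 1
                shx = (mx[g1] + ddx) - 0.5 * (x[f2, e2, 0] + x[f2, e2 + 1, 0])
                shy = (my[g1] + ddy) - 0.5 * (x[f2, e2, 1] + x[f2, e2 + 1, 1])
                q1 = np.empty(3)
                q2 = np.empty(3)
                q1[0] = x[f2, e2, 0] + shx
                q1[1] = x[f2, e2, 1] + shy
                q1[2] = x[f2, e2, 2]
                q2[0] = x[f2, e2 + 1, 0] + shx
                q2[1] = x[f2, e2 + 1, 1] + shy
                q2[2] = x[f2, e2 + 1, 2]
                p1 = np.empty(3)
                p2 = np.empty(3)
                p1[0] = mx[g1] - 0.5 * (x[f1, e1 + 1, 0] - x[f1, e1, 0])
                p1[1] = my[g1] - 0.5 * (x[f1, e1 + 1, 1] - x[f1, e1, 1])
                p1[2] = x[f1, e1, 2]
                p2[0] = mx[g1] + 0.5 * (x[f1, e1 + 1, 0] - x[f1, e1, 0])
                p2[1] = my[g1] + 0.5 * (x[f1, e1 + 1, 1] - x[f1, e1, 1])
                p2[2] = x[f1, e1 + 1, 2]
                if _seg_seg_dist_sq(p1, p2, q1, q2) < cutoff * cutoff:
                    if count >= cap:
                        cap *= 2
                        na = np.empty(cap, dtype=np.int64)
                        nb2 = np.empty(cap, dtype=np.int64)
                        na[:count] = pa[:count]
                        nb2[:count] = pb[:count]
                        pa, pb = na, nb2
                    pa[count] = g1
                    pb[count] = g2
                    count += 1
    out = np.empty((count, 2), dtype=np.int64)
    out[:, 0] = pa[:count]
    out[:, 1] = pb[:count]
    return out


@njit(**_NJIT_FAST)
def add_contact_forces(x, tangents, pairs, theta, epsilon, cap_r, repulsion_only,
                       epsilon_repulsion, width, depth, out):
    """Accumulate LJ capsule contact forces for all candidate pairs.

    Mirrors :func:`trichosim.contact.edge_pair_forces` with the minimum-image
    convention applied to the second edge of each pair.  Returns the maximum
    core penetration ``theta - h`` observed (0 when no overlap).
    """
    n_tri, m, _ = x.shape
    ne = m - 1
    eps = epsilon_repulsion if repulsion_only else epsilon
    cut = 2.0 * theta
    max_pen = 0.0
    a_cand = np.empty(4)
    b_cand = np.empty(4)
    for p in range(pairs.shape[0]):
        g1, g2 = pairs[p, 0], pairs[p, 1]
        f1, e1 = g1 // ne, g1 % ne
        f2, e2 = g2 // ne, g2 % ne
        x1x, x1y, x1z = x[f1, e1, 0], x[f1, e1, 1], x[f1, e1, 2]
        x2x, x2y, x2z = x[f1, e1 + 1, 0], x[f1, e1 + 1, 1], x[f1, e1 + 1, 2]
        x3x, x3y, x3z = x[f2, e2, 0], x[f2, e2, 1], x[f2, e2, 2]
        x4x, x4y, x4z = x[f2, e2 + 1, 0], x[f2, e2 + 1, 1], x[f2, e2 + 1, 2]
        # minimum image shift of edge 2 toward edge 1
        sx = 0.5 * (x3x + x4x) - 0.5 * (x1x + x2x)
        sy = 0.5 * (x3y + x4y) - 0.5 * (x1y + x2y)
        shx = -np.round(sx / width) * width
        shy = -np.round(sy / depth) * depth
        x3x += shx
        x3y += shy
        x4x += shx
        x4y += shy
        t1x, t1y, t1z = tangents[f1, e1, 0], tangents[f1, e1, 1], tangents[f1, e1, 2]
        t2x, t2y, t2z = (tangents[f1, e1 + 1, 0], tangents[f1, e1 + 1, 1],
                         tangents[f1, e1 + 1, 2])
        t3x, t3y, t3z = tangents[f2, e2, 0], tangents[f2, e2, 1], tangents[f2, e2, 2]
        t4x, t4y, t4z = (tangents[f2, e2 + 1, 0], tangents[f2, e2 + 1, 1],
                         tangents[f2, e2 + 1, 2])
        end1a = e1 == 0
        end1b = e1 + 1 == m - 1
        end2a = e2 == 0
        end2b = e2 + 1 == m - 1

        d1x, d1y, d1z = x2x - x1x, x2y - x1y, x2z - x1z
        d2x, d2y, d2z = x4x - x3x, x4y - x3y, x4z - x3z
        rx, ry, rz = x3x - x1x, x3y - x1y, x3z - x1z
        d11 = d1x * d1x + d1y * d1y + d1z * d1z
        d22 = d2x * d2x + d2y * d2y + d2z * d2z
        d12 = d1x * d2x + d1y * d2y + d1z * d2z
        r1 = rx * d1x + ry * d1y + rz * d1z
        r2 = rx * d2x + ry * d2y + rz * d2z
        denom = d11 * d22 - d12 * d12
        n_int = 0
        if denom > 1e-12 * d11 * d22:
            ax = (r1 * d22 - r2 * d12) / denom
            bx = (r1 * d12 - r2 * d11) / denom
            if 0.0 < ax < 1.0 and 0.0 < bx < 1.0:
                a_cand[0] = ax
                b_cand[0] = bx
                n_int = 1
        if n_int == 0:
            # vertex-edge candidates with capsule-domain conditions
            # x3 vs edge1
            r13t1 = rx * t1x + ry * t1y + rz * t1z
            r23x, r23y, r23z = x3x - x2x, x3y - x2y, x3z - x2z
            r23t2 = r23x * t2x + r23y * t2y + r23z * t2z
            a = r1 / d11
            a = 0.0 if a < 0.0 else (1.0 if a > 1.0 else a)
            if ((r13t1 >= 0.0 or (end1a and a == 0.0))
                    and (r23t2 < 0.0 or (end1b and a == 1.0))):
                hx = x3x - (x1x + a * d1x)
                hy = x3y - (x1y + a * d1y)
                hz = x3z - (x1z + a * d1z)
                if (hx * t3x + hy * t3y + hz * t3z <= 0.0) or end2a:
                    a_cand[n_int] = a
                    b_cand[n_int] = 0.0
                    n_int += 1
            # x4 vs edge1
            r14x, r14y, r14z = x4x - x1x, x4y - x1y, x4z - x1z
            r14t1 = r14x * t1x + r14y * t1y + r14z * t1z
            r24x, r24y, r24z = x4x - x2x, x4y - x2y, x4z - x2z
            r24t2 = r24x * t2x + r24y * t2y + r24z * t2z
            a = (r14x * d1x + r14y * d1y + r14z * d1z) / d11
            a = 0.0 if a < 0.0 else (1.0 if a > 1.0 else a)
            if ((r14t1 >= 0.0 or (end1a and a == 0.0))
                    and (r24t2 < 0.0 or (end1b and a == 1.0))):
                hx = x4x - (x1x + a * d1x)
                hy = x4y - (x1y + a * d1y)
                hz = x4z - (x1z + a * d1z)
                if (hx * t4x + hy * t4y + hz * t4z > 0.0) or end2b:
                    a_cand[n_int] = a
                    b_cand[n_int] = 1.0
                    n_int += 1
            # x1 vs edge2
            r31t3 = -(rx * t3x + ry * t3y + rz * t3z)
            r41t4 = -(r14x * t4x + r14y * t4y + r14z * t4z)
            b = -(rx * d2x + ry * d2y + rz * d2z) / d22
            b = 0.0 if b < 0.0 else (1.0 if b > 1.0 else b)
            if ((r31t3 >= 0.0 or (end2a and b == 0.0))
                    and (r41t4 < 0.0 or (end2b and b == 1.0))):
                hx = (x3x + b * d2x) - x1x
                hy = (x3y + b * d2y) - x1y
                hz = (x3z + b * d2z) - x1z
                if (hx * t1x + hy * t1y + hz * t1z <= 0.0) or end1a:
                    dup = False
                    for q in range(n_int):
                        if abs(a_cand[q]) < 1e-12 and abs(b_cand[q] - b) < 1e-12:
                            dup = True
                    if not dup:
                        a_cand[n_int] = 0.0
                        b_cand[n_int] = b
                        n_int += 1
            # x2 vs edge2
            r32x, r32y, r32z = x2x - x3x, x2y - x3y, x2z - x3z
            r32t3 = r32x * t3x + r32y * t3y + r32z * t3z
            r42t4 = -(r24x * t4x + r24y * t4y + r24z * t4z)
            b = (r32x * d2x + r32y * d2y + r32z * d2z) / d22
            b = 0.0 if b < 0.0 else (1.0 if b > 1.0 else b)
            if ((r32t3 >= 0.0 or (end2a and b == 0.0))
                    and (r42t4 < 0.0 or (end2b and b == 1.0))):
                hx = (x3x + b * d2x) - x2x
                hy = (x3y + b * d2y) - x2y
                hz = (x3z + b * d2z) - x2z
                if (hx * t2x + hy * t2y + hz * t2z > 0.0) or end1b:
                    dup = False
                    for q in range(n_int):
                        if abs(a_cand[q] - 1.0) < 1e-12 and abs(b_cand[q] - b) < 1e-12:
                            dup = True
                    if not dup:
                        a_cand[n_int] = 1.0
                        b_cand[n_int] = b
                        n_int += 1

        for q in range(n_int):
            a = a_cand[q]
            b = b_cand[q]
            hx = (x3x + b * d2x) - (x1x + a * d1x)
            hy = (x3y + b * d2y) - (x1y + a * d1y)
            hz = (x3z + b * d2z) - (x1z + a * d1z)
            hn = np.sqrt(hx * hx + hy * hy + hz * hz)
            if hn >= cut or hn < 1e-30:
                continue
            if repulsion_only and hn >= theta:
                continue
            pen = theta - hn
            if pen > max_pen:
                max_pen = pen
            qr = theta / hn
            q7 = qr ** 7
            fmag = 0.5 * eps * (q7 * (qr ** 6) - q7)
            if fmag > cap_r:
                fmag = cap_r
            s = -fmag / hn
            fcx, fcy, fcz = s * hx, s * hy, s * hz
            out[f1, e1, 0] += (1.0 - a) * fcx
            out[f1, e1, 1] += (1.0 - a) * fcy
            out[f1, e1, 2] += (1.0 - a) * fcz
            out[f1, e1 + 1, 0] += a * fcx
            out[f1, e1 + 1, 1] += a * fcy
            out[f1, e1 + 1, 2] += a * fcz
            out[f2, e2, 0] -= (1.0 - b) * fcx
            out[f2, e2, 1] -= (1.0 - b) * fcy
            out[f2, e2, 2] -= (1.0 - b) * fcz
            out[f2, e2 + 1, 0] -= b * fcx
            out[f2, e2 + 1, 1] -= b * fcy
            out[f2, e2 + 1, 2] -= b * fcz
    return max_pen



@njit(**_NJIT_FAST)
def max_displacement_sq(x, ref):
    n_tri, m, _ = x.shape
    best = 0.0
    for f in range(n_tri):
        for i in range(m):
            dx = x[f, i, 0] - ref[f, i, 0]
            dy = x[f, i, 1] - ref[f, i, 1]
            dz = x[f, i, 2] - ref[f, i, 2]
            d2 = dx * dx + dy * dy + dz * dz
            if d2 > best:
                best = d2
    return best
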