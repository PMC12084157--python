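"""Numba Monte Carlo kernels for the dynamically triangulated vesicle.

One sweep = a Metropolis displacement attempt (uniform in a cube of side
``delta``) for every membrane vertex and every filament bead, plus bond
flip attempts on a fraction of the edges.  Energies are in k_BT, lengths
in micrometres:

* bending: kt * sum_edges (1 - cos theta_e), kt = sqrt(3) kappa
* tension: sig * A
* harmonic constraints: ka (A - A0)^2 / A0 + kv (V - V0)^2 / V0
* membrane bonds: hard tether walls [l_min, l_max]
* filament bonds: kb (r - r0)^2; filament bending: kang (1 - cos alpha)
* filament-membrane and filament-filament excluded volume:
  krep (1 - r/rc)^2 for r < rc (purely repulsive, harmonic cap)

Detailed balance holds for every passive term; the only nonequilibrium
ingredient is the externally imposed growth of the filament rest length.
"""

from __future__ import annotations

import numpy as np
from numba import njit

BIG = 1e30


@njit(cache=True, inline="always")
def _tri_area_vol(verts, i, j, k):
    ax = verts[j, 0] - verts[i, 0]
    ay = verts[j, 1] - verts[i, 1]
    az = verts[j, 2] - verts[i, 2]
    bx = verts[k, 0] - verts[i, 0]
    by = verts[k, 1] - verts[i, 1]
    bz = verts[k, 2] - verts[i, 2]
    cx = ay * bz - az * by
    cy = az * bx - ax * bz
    cz = ax * by - ay * bx
    area = 0.5 * np.sqrt(cx * cx + cy * cy + cz * cz)
    # signed volume of tetra (0, i, j, k)
    vx = verts[j, 1] * verts[k, 2] - verts[j, 2] * verts[k, 1]
    vy = verts[j, 2] * verts[k, 0] - verts[j, 0] * verts[k, 2]
    vz = verts[j, 0] * verts[k, 1] - verts[j, 1] * verts[k, 0]
    vol = (verts[i, 0] * vx + verts[i, 1] * vy + verts[i, 2] * vz) / 6.0
    return area, vol


@njit(cache=True, inline="always")
def _normal(verts, i, j, k, out):
    ax = verts[j, 0] - verts[i, 0]
    ay = verts[j, 1] - verts[i, 1]
    az = verts[j, 2] - verts[i, 2]
    bx = verts[k, 0] - verts[i, 0]
    by = verts[k, 1] - verts[i, 1]
    bz = verts[k, 2] - verts[i, 2]
    out[0] = ay * bz - az * by
    out[1] = az * bx - ax * bz
    out[2] = ax * by - ay * bx
    n = np.sqrt(out[0] ** 2 + out[1] ** 2 + out[2] ** 2)
    if n < 1e-14:
        return 0.0
    out[0] /= n
    out[1] /= n
    out[2] /= n
    return n


@njit(cache=True)
def _edge_bend_cos(verts, tris, e_t, e):
    n0 = np.empty(3)
    n1 = np.empty(3)
    t0 = e_t[e, 0]
    t1 = e_t[e, 1]
    ok0 = _normal(verts, tris[t0, 0], tris[t0, 1], tris[t0, 2], n0)
    ok1 = _normal(verts, tris[t1, 0], tris[t1, 1], tris[t1, 2], n1)
    if ok0 == 0.0 or ok1 == 0.0:
        return -2.0  # degenerate flag
    return n0[0] * n1[0] + n0[1] * n1[1] + n0[2] * n1[2]


@njit(cache=True)
def _collect_local_edges(v, v_tri, nvt, tri_edge, buf):
    """Unique edge ids of the triangles incident to v; returns count."""
    n = 0
    for it in range(nvt[v]):
        f = v_tri[v, it]
        for k in range(3):
            e = tri_edge[f, k]
            seen = False
            for m in range(n):
                if buf[m] == e:
                    seen = True
                    break
            if not seen:
                buf[n] = e
                n += 1
    return n


@njit(cache=True)
def _local_geo_energy(v, verts, tris, e_t, v_tri, nvt, tri_edge, kt, buf):
    """Bending over local edges + (area, volume) of incident triangles.

    Returns (E_bend, area_inc, vol_inc, ok)."""
    ne = _collect_local_edges(v, v_tri, nvt, tri_edge, buf)
    eb = 0.0
    for m in range(ne):
        c = _edge_bend_cos(verts, tris, e_t, buf[m])
        if c < -1.5:
            return 0.0, 0.0, 0.0, False
        eb += kt * (1.0 - c)
    area = 0.0
    vol = 0.0
    for it in range(nvt[v]):
        f = v_tri[v, it]
        a, vv = _tri_area_vol(verts, tris[f, 0], tris[f, 1], tris[f, 2])
        if a < 1e-12:
            return 0.0, 0.0, 0.0, False
        area += a
        vol += vv
    return eb, area, vol, True


@njit(cache=True, inline="always")
def _rep_energy_point_beads(p, fil, skip_lo, skip_hi, krep, rc):
    """Repulsion of point p against all beads, skipping indices in
    [skip_lo, skip_hi)."""
    e = 0.0
    rc2 = rc * rc
    for b in range(fil.shape[0]):
        if skip_lo <= b < skip_hi:
            continue
        dx = p[0] - fil[b, 0]
        dy = p[1] - fil[b, 1]
        dz = p[2] - fil[b, 2]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 < rc2:
            r = np.sqrt(r2)
            e += krep * (1.0 - r / rc) ** 2
    return e


@njit(cache=True, inline="always")
def _rep_energy_point_verts(p, verts, krep, rc):
    e = 0.0
    rc2 = rc * rc
    for v in range(verts.shape[0]):
        dx = p[0] - verts[v, 0]
        dy = p[1] - verts[v, 1]
        dz = p[2] - verts[v, 2]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 < rc2:
            r = np.sqrt(r2)
            e += krep * (1.0 - r / rc) ** 2
    return e


@njit(cache=True, inline="always")
def _angle_energy(fil, a, b, c, kang):
    """kang * (1 - cos alpha) for the bend at bead b."""
    ux = fil[b, 0] - fil[a, 0]
    uy = fil[b, 1] - fil[a, 1]
    uz = fil[b, 2] - fil[a, 2]
    vx = fil[c, 0] - fil[b, 0]
    vy = fil[c, 1] - fil[b, 1]
    vz = fil[c, 2] - fil[b, 2]
    nu = np.sqrt(ux * ux + uy * uy + uz * uz)
    nv = np.sqrt(vx * vx + vy * vy + vz * vz)
    if nu < 1e-12 or nv < 1e-12:
        return 0.0
    c_ = (ux * vx + uy * vy + uz * vz) / (nu * nv)
    return kang * (1.0 - c_)


@njit(cache=True)
def _bead_local_energy(b, fil, n_beads, verts, r0_arr, kb, kang, krep, rc):
    chain = b // n_beads
    i = b - chain * n_beads
    lo = chain * n_beads
    r0 = r0_arr[chain]
    e = 0.0
    # bonds to chain neighbours
    for other in (b - 1, b + 1):
        j = other - lo
        if 0 <= j < n_beads:
            dx = fil[b, 0] - fil[other, 0]
            dy = fil[b, 1] - fil[other, 1]
            dz = fil[b, 2] - fil[other, 2]
            r = np.sqrt(dx * dx + dy * dy + dz * dz)
            e += kb * (r - r0) ** 2
    # bending angles involving bead i: centred at i-1, i, i+1
    for c in (i - 1, i, i + 1):
        if 1 <= c < n_beads - 1:
            e += _angle_energy(fil, lo + c - 1, lo + c, lo + c + 1, kang)
    # excluded volume: all membrane vertices + beads outside |di| <= 2 window
    e += _rep_energy_point_verts(fil[b], verts, krep, rc)
    s_lo = lo + max(i - 2, 0)
    s_hi = lo + min(i + 3, n_beads)
    e += _rep_energy_point_beads(fil[b], fil, s_lo, s_hi, krep, rc)
    return e


@njit(cache=True)
def _penalty(A, V, A0, V0, ka, kv):
    return ka * (A - A0) ** 2 / A0 + kv * (V - V0) ** 2 / V0


@njit(cache=True)
def sweep(verts, tris, e_v, e_t, tri_edge, nbr, nnbr, v_tri, nvt,
          fil, n_beads, r0_arr, kb, kang, krep, rc,
          kt, sig, ka, kv, A0, V0, A, V,
          lmin2, lmax2, delta, n_flip_attempts, seed):
    """One Monte Carlo sweep; returns (A, V, acc_v, acc_b, acc_f, att_f)."""
    np.random.seed(seed)
    n_v = verts.shape[0]
    n_e = e_v.shape[0]
    n_b = fil.shape[0]
    buf = np.empty(3 * 16, dtype=np.int64)
    old_pos = np.empty(3)
    acc_v = 0
    acc_b = 0
    acc_f = 0

    # ---- vertex moves -----------------------------------------------------
    for _ in range(n_v):
        v = np.random.randint(0, n_v)
        e_old, a_old, vol_old, ok = _local_geo_energy(
            v, verts, tris, e_t, v_tri, nvt, tri_edge, kt, buf)
        if not ok:
            continue
        rep_old = 0.0
        if n_b > 0:
            rep_old = _rep_energy_point_beads(verts[v], fil, -1, -1, krep, rc)
        for d in range(3):
            old_pos[d] = verts[v, d]
            verts[v, d] += delta * (np.random.random() - 0.5)
        # tether constraint on incident bonds
        reject = False
        for m in range(nnbr[v]):
            u = nbr[v, m]
            dx = verts[v, 0] - verts[u, 0]
            dy = verts[v, 1] - verts[u, 1]
            dz = verts[v, 2] - verts[u, 2]
            r2 = dx * dx + dy * dy + dz * dz
            if r2 < lmin2 or r2 > lmax2:
                reject = True
                break
        if not reject:
            e_new, a_new, vol_new, ok = _local_geo_energy(
                v, verts, tris, e_t, v_tri, nvt, tri_edge, kt, buf)
            if not ok:
                reject = True
        if not reject:
            rep_new = 0.0
            if n_b > 0:
                rep_new = _rep_energy_point_beads(verts[v], fil, -1, -1,
                                                  krep, rc)
            dA = a_new - a_old
            dV = vol_new - vol_old
            dE = (e_new - e_old) + sig * dA + rep_new - rep_old \
                + _penalty(A + dA, V + dV, A0, V0, ka, kv) \
                - _penalty(A, V, A0, V0, ka, kv)
            if dE <= 0.0 or np.random.random() < np.exp(-dE):
                A += dA
                V += dV
                acc_v += 1
            else:
                reject = True
        if reject:
            for d in range(3):
                verts[v, d] = old_pos[d]

    # ---- bead moves -------------------------------------------------------
    for _ in range(n_b):
        b = np.random.randint(0, n_b)
        e_old = _bead_local_energy(b, fil, n_beads, verts, r0_arr, kb, kang,
                                   krep, rc)
        for d in range(3):
            old_pos[d] = fil[b, d]
            fil[b, d] += delta * (np.random.random() - 0.5)
        e_new = _bead_local_energy(b, fil, n_beads, verts, r0_arr, kb, kang,
                                   krep, rc)
        dE = e_new - e_old
        if dE <= 0.0 or np.random.random() < np.exp(-dE):
            acc_b += 1
        else:
            for d in range(3):
                fil[b, d] = old_pos[d]

    # ---- bond flips -------------------------------------------------------
    n0 = np.empty(3)
    n1 = np.empty(3)
    nA = np.empty(3)
    nB = np.empty(3)
    no = np.empty(3)
    for _ in range(n_flip_attempts):
        e = np.random.randint(0, n_e)
        v0 = e_v[e, 0]
        v1 = e_v[e, 1]
        t0 = e_t[e, 0]
        t1 = e_t[e, 1]
        # third vertices
        a = -1
        for k in range(3):
            if tris[t0, k] != v0 and tris[t0, k] != v1:
                a = tris[t0, k]
        b2 = -1
        for k in range(3):
            if tris[t1, k] != v0 and tris[t1, k] != v1:
                b2 = tris[t1, k]
        if a < 0 or b2 < 0 or a == b2:
            continue
        if nnbr[v0] <= 3 or nnbr[v1] <= 3:
            continue
        if nnbr[a] >= nbr.shape[1] or nnbr[b2] >= nbr.shape[1]:
            continue
        already = False
        for m in range(nnbr[a]):
            if nbr[a, m] == b2:
                already = True
                break
        if already:
            continue
        dx = verts[a, 0] - verts[b2, 0]
        dy = verts[a, 1] - verts[b2, 1]
        dz = verts[a, 2] - verts[b2, 2]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 < lmin2 or r2 > lmax2:
            continue
        # ensure canonical orientation: t0 must read (v0, v1, a) cyclically
        c0 = -1
        for k in range(3):
            if tris[t0, k] == v0:
                c0 = k
        if tris[t0, (c0 + 1) % 3] != v1:
            # edge stored opposite to t0's winding; swap v0/v1
            tmp = v0
            v0 = v1
            v1 = tmp
        # rim edges
        e_v0a = -1
        e_av1 = -1
        e_v1b = -1
        e_bv0 = -1
        for k in range(3):
            ee = tri_edge[t0, k]
            if ee == e:
                continue
            if (e_v[ee, 0] == a and e_v[ee, 1] == v0) or \
               (e_v[ee, 0] == v0 and e_v[ee, 1] == a):
                e_v0a = ee
            else:
                e_av1 = ee
        for k in range(3):
            ee = tri_edge[t1, k]
            if ee == e:
                continue
            if (e_v[ee, 0] == b2 and e_v[ee, 1] == v0) or \
               (e_v[ee, 0] == v0 and e_v[ee, 1] == b2):
                e_bv0 = ee
            else:
                e_v1b = ee
        if e_v0a < 0 or e_av1 < 0 or e_v1b < 0 or e_bv0 < 0:
            continue
        # old energies: bending on 5 edges, area/volume of t0, t1
        eb_old = 0.0
        bad = False
        for ee in (e, e_v0a, e_av1, e_v1b, e_bv0):
            c = _edge_bend_cos(verts, tris, e_t, ee)
            if c < -1.5:
                bad = True
                break
            eb_old += kt * (1.0 - c)
        if bad:
            continue
        a_t0, v_t0 = _tri_area_vol(verts, tris[t0, 0], tris[t0, 1], tris[t0, 2])
        a_t1, v_t1 = _tri_area_vol(verts, tris[t1, 0], tris[t1, 1], tris[t1, 2])
        # new triangles tA = (v0, b2, a), tB = (b2, v1, a)
        okA = _normal(verts, v0, b2, a, nA)
        okB = _normal(verts, b2, v1, a, nB)
        if okA == 0.0 or okB == 0.0:
            continue
        a_tA, v_tA = _tri_area_vol(verts, v0, b2, a)
        a_tB, v_tB = _tri_area_vol(verts, b2, v1, a)
        if a_tA < 1e-12 or a_tB < 1e-12:
            continue
        eb_new = kt * (1.0 - (nA[0] * nB[0] + nA[1] * nB[1] + nA[2] * nB[2]))
        # rim edges against their unchanged outer triangles
        bad = False
        for ee, nn in ((e_v0a, nA), (e_av1, nB), (e_v1b, nB), (e_bv0, nA)):
            ot = e_t[ee, 0]
            if ot == t0 or ot == t1:
                ot = e_t[ee, 1]
            okO = _normal(verts, tris[ot, 0], tris[ot, 1], tris[ot, 2], no)
            if okO == 0.0:
                bad = True
                break
            eb_new += kt * (1.0 - (nn[0] * no[0] + nn[1] * no[1] + nn[2] * no[2]))
        if bad:
            continue
        dA = (a_tA + a_tB) - (a_t0 + a_t1)
        dV = (v_tA + v_tB) - (v_t0 + v_t1)
        dE = (eb_new - eb_old) + sig * dA \
            + _penalty(A + dA, V + dV, A0, V0, ka, kv) \
            - _penalty(A, V, A0, V0, ka, kv)
        if dE <= 0.0 or np.random.random() < np.exp(-dE):
            # commit the flip
            tris[t0, 0] = v0
            tris[t0, 1] = b2
            tris[t0, 2] = a
            tris[t1, 0] = b2
            tris[t1, 1] = v1
            tris[t1, 2] = a
            e_v[e, 0] = a
            e_v[e, 1] = b2
            tri_edge[t0, 0] = e_bv0
            tri_edge[t0, 1] = e
            tri_edge[t0, 2] = e_v0a
            tri_edge[t1, 0] = e_v1b
            tri_edge[t1, 1] = e_av1
            tri_edge[t1, 2] = e
            # e_t updates: e_av1 moves t0 -> t1; e_bv0 moves t1 -> t0
            for s in range(2):
                if e_t[e_av1, s] == t0:
                    e_t[e_av1, s] = t1
                if e_t[e_bv0, s] == t1:
                    e_t[e_bv0, s] = t0
            # neighbour lists: drop v0-v1, add a-b2
            for m in range(nnbr[v0]):
                if nbr[v0, m] == v1:
                    nbr[v0, m] = nbr[v0, nnbr[v0] - 1]
                    nnbr[v0] -= 1
                    break
            for m in range(nnbr[v1]):
                if nbr[v1, m] == v0:
                    nbr[v1, m] = nbr[v1, nnbr[v1] - 1]
                    nnbr[v1] -= 1
                    break
            nbr[a, nnbr[a]] = b2
            nnbr[a] += 1
            nbr[b2, nnbr[b2]] = a
            nnbr[b2] += 1
            # incidence: v1 loses t0 (gains nothing); b2 gains t0;
            # v0 loses t1; a gains t1
            for m in range(nvt[v1]):
                if v_tri[v1, m] == t0:
                    v_tri[v1, m] = v_tri[v1, nvt[v1] - 1]
                    nvt[v1] -= 1
                    break
            v_tri[b2, nvt[b2]] = t0
            nvt[b2] += 1
            for m in range(nvt[v0]):
                if v_tri[v0, m] == t1:
                    v_tri[v0, m] = v_tri[v0, nvt[v0] - 1]
                    nvt[v0] -= 1
                    break
            v_tri[a, nvt[a]] = t1
            nvt[a] += 1
            A += dA
            V += dV
            acc_f += 1

    return A, V, acc_v, acc_b, acc_f


@njit(cache=True)
def active_forces(verts, fil, krep, rc):
    """Per-vertex repulsive force (kBT/um) exerted by the filament beads."""
    f = np.zeros((verts.shape[0], 3))
    rc2 = rc * rc
    for v in range(verts.shape[0]):
        for b in range(fil.shape[0]):
            dx = verts[v, 0] - fil[b, 0]
            dy = verts[v, 1] - fil[b, 1]
            dz = verts[v, 2] - fil[b, 2]
            r2 = dx * dx + dy * dy + dz * dz
            if r2 < rc2 and r2 > 1e-20:
                r = np.sqrt(r2)
                mag = 2.0 * krep * (1.0 - r / rc) / rc  # -dU/dr
                f[v, 0] += mag * dx / r
                f[v, 1] += mag * dy / r
                f[v, 2] += mag * dz / r
    return f


@njit(cache=True)
def raycast_contour(verts, tris, center, m_phi):
    """Equatorial contour by casting rays from center in the z=0 plane.

    Returns radii (m_phi,), NaN where a ray misses every triangle (the
    caller flags such frames).  The farthest intersection along each ray
    is kept, which handles transient overhangs."""
    out = np.full(m_phi, np.nan)
    for m in range(m_phi):
        phi = 2.0 * np.pi * m / m_phi
        dx = np.cos(phi)
        dy = np.sin(phi)
        best = -1.0
        for f in range(tris.shape[0]):
            i0 = tris[f, 0]
            i1 = tris[f, 1]
            i2 = tris[f, 2]
            # Moeller-Trumbore with ray origin=center, dir=(dx,dy,0)
            e1x = verts[i1, 0] - verts[i0, 0]
            e1y = verts[i1, 1] - verts[i0, 1]
            e1z = verts[i1, 2] - verts[i0, 2]
            e2x = verts[i2, 0] - verts[i0, 0]
            e2y = verts[i2, 1] - verts[i0, 1]
            e2z = verts[i2, 2] - verts[i0, 2]
            # p = dir x e2
            px = dy * e2z  # dir_z = 0
            py = -dx * e2z
            pz = dx * e2y - dy * e2x
            det = e1x * px + e1y * py + e1z * pz
            if -1e-12 < det < 1e-12:
                continue
            inv = 1.0 / det
            tx = center[0] - verts[i0, 0]
            ty = center[1] - verts[i0, 1]
            tz = center[2] - verts[i0, 2]
            u = (tx * px + ty * py + tz * pz) * inv
            if u < -1e-9 or u > 1.0 + 1e-9:
                continue
            qx = ty * e1z - tz * e1y
            qy = tz * e1x - tx * e1z
            qz = tx * e1y - ty * e1x
            v = (dx * qx + dy * qy) * inv  # dir_z = 0
            if v < -1e-9 or u + v > 1.0 + 1e-9:
                continue
            t = (e2x * qx + e2y * qy + e2z * qz) * inv
            if t > 1e-9 and t > best:
                best = t
        if best > 0.0:
            out[m] = best
    return out
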