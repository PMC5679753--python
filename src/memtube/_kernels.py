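"""Numba kernels for the Metropolis Monte Carlo sweep.

Everything here operates on plain arrays; the object-facing API lives in
``engine``.  Incremental (local) energy evaluation makes a sweep O(V); the
vectorised implementations in ``energy`` are the reference the kernels are
tested against.

Array conventions
-----------------
pos (V,3) bead positions, z periodic with period L; tri (F,3) CCW triangles;
edges (E,2); edge_tri (E,2); tri_edges (F,3); v_tri/v_tri_n vertex->triangle
incidence.  Proteins: pc (N,3) middle-sphere positions, rot (N,3,3) local->
world rotations, theta (N) hinge angles, off/bdir (N,5,3) world-frame sphere
offsets from the centre and binding directions.

ep (energy parameter vector):
  0 kappa, 1 gamma, 2 eps, 3 cos_theta_pr, 4 k_flex, 5 theta_eq, 6 k_cp,
  7 R_eq, 8 band_frac_lo, 9 band_frac_hi, 10 r_cut, 11 d_min(sphere-bead),
  12 D_col, 13 l_min, 14 l_max, 15 sigma_hc, 16 R_pr, 17 arc_step
mp (move parameter vector):
  0 amp_vertex, 1 amp_prot_trans, 2 amp_rot, 3 amp_wing, 4 amp_box,
  5 L_min_box, 6 L_max_box, 7 protein lateral cage radius
en (energy accumulator): 0 U_bend, 1 area A, 2 U_adh, 3 U_flex, 4 U_cp
gf (cell grid floats): 0 x0, 1 y0, 2 cell_size_xy, 3 cell_size_z
gi (cell grid ints): 0 ncx, 1 ncy, 2 ncz

Move kind codes: 0 vertex, 1 flip, 2 protein translate, 3 protein rotate,
4 wing, 5 box rescale.
"""

import numpy as np
from numba import njit

BIG = 1e30  # rejection sentinel for Delta U


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

@njit(inline="always")
def _miz(dz, L):
    return dz - L * np.floor(dz / L + 0.5)


@njit(inline="always")
def _get(pos, v, vsub, psub, k):
    if v == vsub:
        return psub[k]
    return pos[v, k]


@njit
def _tri_na(pos, tri, t, L, vsub, psub, nout):
    """Unit normal (into nout) and area of triangle t, vsub's position
    replaced by psub (vsub = -1 for no substitution)."""
    a = tri[t, 0]
    b = tri[t, 1]
    c = tri[t, 2]
    ax = _get(pos, a, vsub, psub, 0)
    ay = _get(pos, a, vsub, psub, 1)
    az = _get(pos, a, vsub, psub, 2)
    d1x = _get(pos, b, vsub, psub, 0) - ax
    d1y = _get(pos, b, vsub, psub, 1) - ay
    d1z = _miz(_get(pos, b, vsub, psub, 2) - az, L)
    d2x = _get(pos, c, vsub, psub, 0) - ax
    d2y = _get(pos, c, vsub, psub, 1) - ay
    d2z = _miz(_get(pos, c, vsub, psub, 2) - az, L)
    nx = d1y * d2z - d1z * d2y
    ny = d1z * d2x - d1x * d2z
    nz = d1x * d2y - d1y * d2x
    nrm = np.sqrt(nx * nx + ny * ny + nz * nz)
    if nrm < 1e-14:
        nout[0] = 0.0
        nout[1] = 0.0
        nout[2] = 0.0
        return 0.0
    nout[0] = nx / nrm
    nout[1] = ny / nrm
    nout[2] = nz / nrm
    return 0.5 * nrm


@njit
def _edge_bend(pos, tri, edge_tri, e, L, vsub, psub, n1, n2):
    """1 - n_i.n_j for edge e (with optional vertex substitution)."""
    _tri_na(pos, tri, edge_tri[e, 0], L, vsub, psub, n1)
    _tri_na(pos, tri, edge_tri[e, 1], L, vsub, psub, n2)
    return 1.0 - (n1[0] * n2[0] + n1[1] * n2[1] + n1[2] * n2[2])


@njit
def _tri_pair_bend(pos, L, a1, b1, c1, a2, b2, c2, n1, n2):
    """1 - n1.n2 for two triangles given by vertex triples."""
    tloc = np.empty((2, 3), dtype=np.int64)
    tloc[0, 0] = a1
    tloc[0, 1] = b1
    tloc[0, 2] = c1
    tloc[1, 0] = a2
    tloc[1, 1] = b2
    tloc[1, 2] = c2
    dummy = np.empty(3)
    _tri_na(pos, tloc, 0, L, -1, dummy, n1)
    _tri_na(pos, tloc, 1, L, -1, dummy, n2)
    return 1.0 - (n1[0] * n2[0] + n1[1] * n2[1] + n1[2] * n2[2])


# ---------------------------------------------------------------------------
# full-system evaluations (used at init and for box moves)
# ---------------------------------------------------------------------------

@njit
def full_bend(pos, tri, edge_tri, L):
    n1 = np.empty(3)
    n2 = np.empty(3)
    dummy = np.empty(3)
    s = 0.0
    for e in range(edge_tri.shape[0]):
        s += _edge_bend(pos, tri, edge_tri, e, L, -1, dummy, n1, n2)
    return s


@njit
def full_area(pos, tri, L):
    n = np.empty(3)
    dummy = np.empty(3)
    s = 0.0
    for t in range(tri.shape[0]):
        s += _tri_na(pos, tri, t, L, -1, dummy, n)
    return s


@njit
def full_adhesion(pos, L, pc, off, bdir, eps, cos_thpr, rcut, dmin):
    """Total adhesion energy; returns (energy, ok) with ok False on overlap."""
    U = 0.0
    rc2 = rcut * rcut
    dm2 = dmin * dmin
    for i in range(pc.shape[0]):
        for s in range(off.shape[1]):
            sx = pc[i, 0] + off[i, s, 0]
            sy = pc[i, 1] + off[i, s, 1]
            sz = pc[i, 2] + off[i, s, 2]
            for v in range(pos.shape[0]):
                dx = pos[v, 0] - sx
                dy = pos[v, 1] - sy
                dz = _miz(pos[v, 2] - sz, L)
                r2 = dx * dx + dy * dy + dz * dz
                if r2 < dm2 - 1e-9:
                    return 0.0, False
                if r2 <= rc2:
                    r = np.sqrt(r2)
                    ca = (dx * bdir[i, s, 0] + dy * bdir[i, s, 1]
                          + dz * bdir[i, s, 2]) / r
                    if ca >= cos_thpr - 1e-12:
                        q = dm2 / r2
                        U -= eps * q * q * q
    return U, True


@njit
def full_cp(pos, L, kcp, Req, flo, fhi):
    if kcp == 0.0:
        return 0.0
    lo = flo * L
    hi = fhi * L
    s = 0.0
    for v in range(pos.shape[0]):
        z = pos[v, 2] % L
        if lo <= z <= hi:
            R = np.sqrt(pos[v, 0] ** 2 + pos[v, 1] ** 2)
            s += 0.5 * kcp * (R - Req) ** 2
    return s


@njit
def check_tethers(pos, edges, L, lmin, lmax):
    for e in range(edges.shape[0]):
        i = edges[e, 0]
        j = edges[e, 1]
        dx = pos[j, 0] - pos[i, 0]
        dy = pos[j, 1] - pos[i, 1]
        dz = _miz(pos[j, 2] - pos[i, 2], L)
        l2 = dx * dx + dy * dy + dz * dz
        if l2 <= lmin * lmin or l2 >= lmax * lmax:
            return False
    return True


@njit
def check_sphere_sphere(pc, off, dcol, L):
    d2min = dcol * dcol
    N = pc.shape[0]
    for i in range(N):
        for j in range(i + 1, N):
            for s in range(off.shape[1]):
                for t in range(off.shape[1]):
                    dx = pc[i, 0] + off[i, s, 0] - pc[j, 0] - off[j, t, 0]
                    dy = pc[i, 1] + off[i, s, 1] - pc[j, 1] - off[j, t, 1]
                    dz = _miz(pc[i, 2] + off[i, s, 2]
                              - pc[j, 2] - off[j, t, 2], L)
                    if dx * dx + dy * dy + dz * dz < d2min - 1e-9:
                        return False
    return True


# ---------------------------------------------------------------------------
# cell list (beads only; serves the bead-bead hard core)
# ---------------------------------------------------------------------------

@njit(inline="always")
def _cell_of(x, y, z, L, gf, gi):
    ix = int(np.floor((x - gf[0]) / gf[2]))
    iy = int(np.floor((y - gf[1]) / gf[2]))
    if ix < 0 or ix >= gi[0] or iy < 0 or iy >= gi[1]:
        return -1
    iz = int((z % L) / gf[3])
    if iz >= gi[2]:
        iz = gi[2] - 1
    return (ix * gi[1] + iy) * gi[2] + iz


@njit
def build_cells(pos, L, gf, gi, head, nxt, prv, bead_cell):
    head[:] = -1
    for v in range(pos.shape[0]):
        c = _cell_of(pos[v, 0], pos[v, 1], pos[v, 2], L, gf, gi)
        bead_cell[v] = c
        if c < 0:
            continue
        nxt[v] = head[c]
        prv[v] = -1
        if head[c] >= 0:
            prv[head[c]] = v
        head[c] = v


@njit
def _cells_ok(pos, L, gf, gi, head, nxt, bead_cell, sigma_hc):
    """Hard-core check over all bead pairs via the cell list."""
    s2 = sigma_hc * sigma_hc
    ncz = gi[2]
    for v in range(pos.shape[0]):
        c = bead_cell[v]
        if c < 0:
            return False
        cz = c % ncz
        cxy = c // ncz
        cy = cxy % gi[1]
        cx = cxy // gi[1]
        for dx in range(-1, 2):
            nx_ = cx + dx
            if nx_ < 0 or nx_ >= gi[0]:
                continue
            for dy in range(-1, 2):
                ny_ = cy + dy
                if ny_ < 0 or ny_ >= gi[1]:
                    continue
                for dz in range(-1, 2):
                    nz_ = (cz + dz) % ncz
                    w = head[(nx_ * gi[1] + ny_) * ncz + nz_]
                    while w >= 0:
                        if w > v:
                            ddx = pos[w, 0] - pos[v, 0]
                            ddy = pos[w, 1] - pos[v, 1]
                            ddz = _miz(pos[w, 2] - pos[v, 2], L)
                            if ddx * ddx + ddy * ddy + ddz * ddz < s2 - 1e-12:
                                return False
                        w = nxt[w]
    return True


@njit
def _move_bead_cell(v, c_new, head, nxt, prv, bead_cell):
    c_old = bead_cell[v]
    if c_old == c_new:
        return
    if c_old >= 0:
        p = prv[v]
        n = nxt[v]
        if p >= 0:
            nxt[p] = n
        else:
            head[c_old] = n
        if n >= 0:
            prv[n] = p
    bead_cell[v] = c_new
    if c_new >= 0:
        nxt[v] = head[c_new]
        prv[v] = -1
        if head[c_new] >= 0:
            prv[head[c_new]] = v
        head[c_new] = v


# ---------------------------------------------------------------------------
# protein local geometry (must match proteins.local_geometry exactly)
# ---------------------------------------------------------------------------

@njit
def protein_local(Rpr, alpha, theta_eq, theta, off, bdir):
    for s in range(5):
        ang = (s - 2) * alpha
        off[s, 0] = Rpr * (1.0 - np.cos(ang))
        off[s, 1] = 0.0
        off[s, 2] = -Rpr * np.sin(ang)
        bdir[s, 0] = np.cos(ang)
        bdir[s, 1] = 0.0
        bdir[s, 2] = np.sin(ang)
    delta = theta - theta_eq
    if delta != 0.0:
        for side in range(2):
            phi = 0.5 * delta if side == 0 else -0.5 * delta
            c = np.cos(phi)
            s_ = np.sin(phi)
            lo = 0 if side == 0 else 3
            hi = 2 if side == 0 else 5
            for s in range(lo, hi):
                x = off[s, 0]
                z = off[s, 2]
                off[s, 0] = c * x + s_ * z
                off[s, 2] = -s_ * x + c * z
                x = bdir[s, 0]
                z = bdir[s, 2]
                bdir[s, 0] = c * x + s_ * z
                bdir[s, 2] = -s_ * x + c * z


@njit
def _rodrigues(ux, uy, uz, angle, R):
    c = np.cos(angle)
    s = np.sin(angle)
    t = 1.0 - c
    R[0, 0] = c + ux * ux * t
    R[0, 1] = ux * uy * t - uz * s
    R[0, 2] = ux * uz * t + uy * s
    R[1, 0] = uy * ux * t + uz * s
    R[1, 1] = c + uy * uy * t
    R[1, 2] = uy * uz * t - ux * s
    R[2, 0] = uz * ux * t - uy * s
    R[2, 1] = uz * uy * t + ux * s
    R[2, 2] = c + uz * uz * t


# ---------------------------------------------------------------------------
# per-protein adhesion (one protein against every bead) and constraints
# ---------------------------------------------------------------------------

@njit
def _protein_adh(pos, L, cx, cy, cz, off_i, bdir_i, eps, cos_thpr, rcut, dmin):
    """Adhesion of one protein; returns (U, ok) with ok False on overlap."""
    U = 0.0
    rc2 = rcut * rcut
    dm2 = dmin * dmin
    for s in range(off_i.shape[0]):
        sx = cx + off_i[s, 0]
        sy = cy + off_i[s, 1]
        sz = cz + off_i[s, 2]
        for v in range(pos.shape[0]):
            dx = pos[v, 0] - sx
            dy = pos[v, 1] - sy
            dz = _miz(pos[v, 2] - sz, L)
            r2 = dx * dx + dy * dy + dz * dz
            if r2 < dm2 - 1e-9:
                return 0.0, False
            if r2 <= rc2:
                r = np.sqrt(r2)
                ca = (dx * bdir_i[s, 0] + dy * bdir_i[s, 1]
                      + dz * bdir_i[s, 2]) / r
                if ca >= cos_thpr - 1e-12:
                    q = dm2 / r2
                    U -= eps * q * q * q
    return U, True


@njit
def _protein_vs_others(pc, off, i, cx, cy, cz, off_i, dcol, L):
    """True if protein i at trial placement overlaps any other protein."""
    d2 = dcol * dcol
    for j in range(pc.shape[0]):
        if j == i:
            continue
        for s in range(5):
            sx = cx + off_i[s, 0]
            sy = cy + off_i[s, 1]
            sz = cz + off_i[s, 2]
            for t in range(5):
                dx = pc[j, 0] + off[j, t, 0] - sx
                dy = pc[j, 1] + off[j, t, 1] - sy
                dz = _miz(pc[j, 2] + off[j, t, 2] - sz, L)
                if dx * dx + dy * dy + dz * dz < d2 - 1e-9:
                    return True
    return False


# ---------------------------------------------------------------------------
# the sweep
# ---------------------------------------------------------------------------

@njit
def run_moves(
    pos, tri, tri_edges, edges, edge_tri, v_tri, v_tri_n, box,
    pc, rot, theta, off, bdir,
    ep, mp,
    head, nxt, prv, bead_cell, gf, gi,
    kinds, targets, u,
    en, acc,
):
    """Execute one block of Metropolis moves; mutates state arrays in place.

    kinds/targets/u supply all randomness (generated by the caller); en is
    the running energy accumulator, acc the (kind, [attempts, accepts])
    counter.  Returns nothing; everything is updated in place.
    """
    L = box[0]
    kappa = ep[0]
    gamma = ep[1]
    eps = ep[2]
    cos_thpr = ep[3]
    kflex = ep[4]
    theta_eq = ep[5]
    kcp = ep[6]
    Req = ep[7]
    flo = ep[8]
    fhi = ep[9]
    rcut = ep[10]
    dmin = ep[11]
    dcol = ep[12]
    lmin = ep[13]
    lmax = ep[14]
    sig = ep[15]
    Rpr = ep[16]
    alpha = ep[17]

    n1 = np.empty(3)
    n2 = np.empty(3)
    psub = np.empty(3)
    ebuf = np.empty(96, dtype=np.int64)
    nrm_old = np.empty((v_tri.shape[1], 3))
    nrm_new = np.empty((v_tri.shape[1], 3))
    off_t = np.empty((5, 3))
    bdir_t = np.empty((5, 3))
    off_l = np.empty((5, 3))
    bdir_l = np.empty((5, 3))
    Rd = np.empty((3, 3))
    V = pos.shape[0]
    NP = pc.shape[0]

    for m in range(kinds.shape[0]):
        kind = kinds[m]
        acc[kind, 0] += 1

        # ----------------------------------------------------- vertex move
        if kind == 0:
            v = targets[m]
            amp = mp[0]
            psub[0] = pos[v, 0] + amp * (2.0 * u[m, 0] - 1.0)
            psub[1] = pos[v, 1] + amp * (2.0 * u[m, 1] - 1.0)
            psub[2] = (pos[v, 2] + amp * (2.0 * u[m, 2] - 1.0)) % L
            c_new = _cell_of(psub[0], psub[1], psub[2], L, gf, gi)
            if c_new < 0:
                continue
            # tether bounds on incident edges
            nt = v_tri_n[v]
            ok = True
            for k in range(nt):
                t = v_tri[v, k]
                for q in range(3):
                    e = tri_edges[t, q]
                    a = edges[e, 0]
                    b = edges[e, 1]
                    if a == v or b == v:
                        w = b if a == v else a
                        dx = pos[w, 0] - psub[0]
                        dy = pos[w, 1] - psub[1]
                        dz = _miz(pos[w, 2] - psub[2], L)
                        l2 = dx * dx + dy * dy + dz * dz
                        if l2 <= lmin * lmin or l2 >= lmax * lmax:
                            ok = False
                            break
                if not ok:
                    break
            if not ok:
                continue
            # bead-bead hard core via cell list
            cz_ = c_new % gi[2]
            cxy = c_new // gi[2]
            cy_ = cxy % gi[1]
            cx_ = cxy // gi[1]
            s2 = sig * sig
            for dxc in range(-1, 2):
                nx_ = cx_ + dxc
                if nx_ < 0 or nx_ >= gi[0]:
                    continue
                for dyc in range(-1, 2):
                    ny_ = cy_ + dyc
                    if ny_ < 0 or ny_ >= gi[1]:
                        continue
                    for dzc in range(-1, 2):
                        nz_ = (cz_ + dzc) % gi[2]
                        w = head[(nx_ * gi[1] + ny_) * gi[2] + nz_]
                        while w >= 0:
                            if w != v:
                                ddx = pos[w, 0] - psub[0]
                                ddy = pos[w, 1] - psub[1]
                                ddz = _miz(pos[w, 2] - psub[2], L)
                                if ddx * ddx + ddy * ddy + ddz * ddz < s2 - 1e-12:
                                    ok = False
                                    break
                            w = nxt[w]
                        if not ok:
                            break
                    if not ok:
                        break
                if not ok:
                    break
            if not ok:
                continue
            # adhesion + sphere-bead hard core (loop over all spheres)
            dadh = 0.0
            dm2 = dmin * dmin
            rc2 = rcut * rcut
            for i in range(NP):
                for s in range(5):
                    sx = pc[i, 0] + off[i, s, 0]
                    sy = pc[i, 1] + off[i, s, 1]
                    sz = pc[i, 2] + off[i, s, 2]
                    # new
                    dx = psub[0] - sx
                    dy = psub[1] - sy
                    dz = _miz(psub[2] - sz, L)
                    r2 = dx * dx + dy * dy + dz * dz
                    if r2 < dm2 - 1e-9:
                        ok = False
                        break
                    if r2 <= rc2:
                        r = np.sqrt(r2)
                        ca = (dx * bdir[i, s, 0] + dy * bdir[i, s, 1]
                              + dz * bdir[i, s, 2]) / r
                        if ca >= cos_thpr - 1e-12:
                            q = dm2 / r2
                            dadh -= eps * q * q * q
                    # old
                    dx = pos[v, 0] - sx
                    dy = pos[v, 1] - sy
                    dz = _miz(pos[v, 2] - sz, L)
                    r2 = dx * dx + dy * dy + dz * dz
                    if r2 <= rc2:
                        r = np.sqrt(r2)
                        ca = (dx * bdir[i, s, 0] + dy * bdir[i, s, 1]
                              + dz * bdir[i, s, 2]) / r
                        if ca >= cos_thpr - 1e-12:
                            q = dm2 / r2
                            dadh += eps * q * q * q
                if not ok:
                    break
            if not ok:
                continue
            # affected edges: all edges of incident triangles
            ne = 0
            for k in range(nt):
                t = v_tri[v, k]
                for q in range(3):
                    e = tri_edges[t, q]
                    seen = False
                    for x in range(ne):
                        if ebuf[x] == e:
                            seen = True
                            break
                    if not seen:
                        ebuf[ne] = e
                        ne += 1
            # cache incident-triangle normals before/after the displacement
            darea = 0.0
            for k in range(nt):
                t = v_tri[v, k]
                darea -= _tri_na(pos, tri, t, L, -1, psub, nrm_old[k])
                darea += _tri_na(pos, tri, t, L, v, psub, nrm_new[k])
            dbend = 0.0
            for x in range(ne):
                e = ebuf[x]
                ta = edge_tri[e, 0]
                tb = edge_tri[e, 1]
                ka = -1
                kb = -1
                for k in range(nt):
                    if v_tri[v, k] == ta:
                        ka = k
                    if v_tri[v, k] == tb:
                        kb = k
                if ka >= 0:
                    ax_o, ay_o, az_o = nrm_old[ka, 0], nrm_old[ka, 1], nrm_old[ka, 2]
                    ax_n, ay_n, az_n = nrm_new[ka, 0], nrm_new[ka, 1], nrm_new[ka, 2]
                else:
                    _tri_na(pos, tri, ta, L, -1, psub, n1)
                    ax_o, ay_o, az_o = n1[0], n1[1], n1[2]
                    ax_n, ay_n, az_n = ax_o, ay_o, az_o
                if kb >= 0:
                    bx_o, by_o, bz_o = nrm_old[kb, 0], nrm_old[kb, 1], nrm_old[kb, 2]
                    bx_n, by_n, bz_n = nrm_new[kb, 0], nrm_new[kb, 1], nrm_new[kb, 2]
                else:
                    _tri_na(pos, tri, tb, L, -1, psub, n2)
                    bx_o, by_o, bz_o = n2[0], n2[1], n2[2]
                    bx_n, by_n, bz_n = bx_o, by_o, bz_o
                dbend -= 1.0 - (ax_o * bx_o + ay_o * by_o + az_o * bz_o)
                dbend += 1.0 - (ax_n * bx_n + ay_n * by_n + az_n * bz_n)
            dcp = 0.0
            if kcp > 0.0:
                lo = flo * L
                hi = fhi * L
                zo = pos[v, 2] % L
                if lo <= zo <= hi:
                    R = np.sqrt(pos[v, 0] ** 2 + pos[v, 1] ** 2)
                    dcp -= 0.5 * kcp * (R - Req) ** 2
                zn = psub[2] % L
                if lo <= zn <= hi:
                    R = np.sqrt(psub[0] ** 2 + psub[1] ** 2)
                    dcp += 0.5 * kcp * (R - Req) ** 2
            du = kappa * dbend + gamma * darea + dadh + dcp
            if du <= 0.0 or u[m, 3] < np.exp(-du):
                pos[v, 0] = psub[0]
                pos[v, 1] = psub[1]
                pos[v, 2] = psub[2]
                _move_bead_cell(v, c_new, head, nxt, prv, bead_cell)
                en[0] += kappa * dbend
                en[1] += darea
                en[2] += dadh
                en[4] += dcp
                acc[kind, 1] += 1

        # ------------------------------------------------------- edge flip
        elif kind == 1:
            e = targets[m]
            t1 = edge_tri[e, 0]
            t2 = edge_tri[e, 1]
            ue = edges[e, 0]
            ve = edges[e, 1]
            # orient a->b in t1
            a = -1
            b = -1
            for k in range(3):
                p_ = tri[t1, k]
                q_ = tri[t1, (k + 1) % 3]
                if p_ == ue and q_ == ve:
                    a = ue
                    b = ve
                    break
                if p_ == ve and q_ == ue:
                    a = ve
                    b = ue
                    break
            c = -1
            d = -1
            for k in range(3):
                if tri[t1, k] != a and tri[t1, k] != b:
                    c = tri[t1, k]
                if tri[t2, k] != a and tri[t2, k] != b:
                    d = tri[t2, k]
            if c == d:
                continue
            # degree floor / table capacity
            if v_tri_n[a] <= 3 or v_tri_n[b] <= 3:
                continue
            if v_tri_n[c] >= v_tri.shape[1] or v_tri_n[d] >= v_tri.shape[1]:
                continue
            # duplicate edge (c and d already share a triangle)
            dup = False
            for k in range(v_tri_n[c]):
                t = v_tri[c, k]
                for q in range(3):
                    if tri[t, q] == d:
                        dup = True
                        break
                if dup:
                    break
            if dup:
                continue
            # tether bound on the new diagonal
            dx = pos[d, 0] - pos[c, 0]
            dy = pos[d, 1] - pos[c, 1]
            dz = _miz(pos[d, 2] - pos[c, 2], L)
            l2 = dx * dx + dy * dy + dz * dz
            if l2 <= lmin * lmin or l2 >= lmax * lmax:
                continue
            # find boundary edges and their external triangles
            e_ca = -1
            e_bc = -1
            e_ad = -1
            e_db = -1
            for k in range(3):
                eid = tri_edges[t1, k]
                p_ = edges[eid, 0]
                q_ = edges[eid, 1]
                if (p_ == c and q_ == a) or (p_ == a and q_ == c):
                    e_ca = eid
                elif (p_ == b and q_ == c) or (p_ == c and q_ == b):
                    e_bc = eid
                eid = tri_edges[t2, k]
                p_ = edges[eid, 0]
                q_ = edges[eid, 1]
                if (p_ == a and q_ == d) or (p_ == d and q_ == a):
                    e_ad = eid
                elif (p_ == d and q_ == b) or (p_ == b and q_ == d):
                    e_db = eid
            x_ca = edge_tri[e_ca, 0] if edge_tri[e_ca, 0] != t1 else edge_tri[e_ca, 1]
            x_bc = edge_tri[e_bc, 0] if edge_tri[e_bc, 0] != t1 else edge_tri[e_bc, 1]
            x_ad = edge_tri[e_ad, 0] if edge_tri[e_ad, 0] != t2 else edge_tri[e_ad, 1]
            x_db = edge_tri[e_db, 0] if edge_tri[e_db, 0] != t2 else edge_tri[e_db, 1]
            dummy = np.empty(3)
            # old bending of the 5 edges
            old = (
                _edge_bend(pos, tri, edge_tri, e, L, -1, dummy, n1, n2)
                + _edge_bend(pos, tri, edge_tri, e_ca, L, -1, dummy, n1, n2)
                + _edge_bend(pos, tri, edge_tri, e_bc, L, -1, dummy, n1, n2)
                + _edge_bend(pos, tri, edge_tri, e_ad, L, -1, dummy, n1, n2)
                + _edge_bend(pos, tri, edge_tri, e_db, L, -1, dummy, n1, n2)
            )
            # old area of t1, t2
            a_old = (_tri_na(pos, tri, t1, L, -1, dummy, n1)
                     + _tri_na(pos, tri, t2, L, -1, dummy, n1))
            # new triangles: t1' = (c,a,d), t2' = (d,b,c)
            new = _tri_pair_bend(pos, L, c, a, d, d, b, c, n1, n2)
            new += _tri_pair_bend(pos, L, c, a, d,
                                  tri[x_ca, 0], tri[x_ca, 1], tri[x_ca, 2], n1, n2)
            new += _tri_pair_bend(pos, L, c, a, d,
                                  tri[x_ad, 0], tri[x_ad, 1], tri[x_ad, 2], n1, n2)
            new += _tri_pair_bend(pos, L, d, b, c,
                                  tri[x_bc, 0], tri[x_bc, 1], tri[x_bc, 2], n1, n2)
            new += _tri_pair_bend(pos, L, d, b, c,
                                  tri[x_db, 0], tri[x_db, 1], tri[x_db, 2], n1, n2)
            tloc = np.empty((2, 3), dtype=np.int64)
            tloc[0, 0] = c
            tloc[0, 1] = a
            tloc[0, 2] = d
            tloc[1, 0] = d
            tloc[1, 1] = b
            tloc[1, 2] = c
            a_new = (_tri_na(pos, tloc, 0, L, -1, dummy, n1)
                     + _tri_na(pos, tloc, 1, L, -1, dummy, n1))
            du = kappa * (new - old) + gamma * (a_new - a_old)
            if du <= 0.0 or u[m, 0] < np.exp(-du):
                tri[t1, 0] = c
                tri[t1, 1] = a
                tri[t1, 2] = d
                tri_edges[t1, 0] = e_ca
                tri_edges[t1, 1] = e_ad
                tri_edges[t1, 2] = e
                tri[t2, 0] = d
                tri[t2, 1] = b
                tri[t2, 2] = c
                tri_edges[t2, 0] = e_db
                tri_edges[t2, 1] = e_bc
                tri_edges[t2, 2] = e
                edges[e, 0] = c if c < d else d
                edges[e, 1] = d if c < d else c
                for pair in range(2):
                    eid = e_ad if pair == 0 else e_bc
                    oldt = t2 if pair == 0 else t1
                    newt = t1 if pair == 0 else t2
                    if edge_tri[eid, 0] == oldt:
                        edge_tri[eid, 0] = newt
                    else:
                        edge_tri[eid, 1] = newt
                # v_tri updates: a loses t2, b loses t1, c gains t2, d gains t1
                for pair in range(2):
                    vtx = a if pair == 0 else b
                    lost = t2 if pair == 0 else t1
                    n_ = v_tri_n[vtx]
                    for k in range(n_):
                        if v_tri[vtx, k] == lost:
                            v_tri[vtx, k] = v_tri[vtx, n_ - 1]
                            v_tri[vtx, n_ - 1] = -1
                            break
                    v_tri_n[vtx] = n_ - 1
                for pair in range(2):
                    vtx = c if pair == 0 else d
                    gained = t2 if pair == 0 else t1
                    v_tri[vtx, v_tri_n[vtx]] = gained
                    v_tri_n[vtx] += 1
                en[0] += kappa * (new - old)
                en[1] += a_new - a_old
                acc[kind, 1] += 1

        # ------------------------------------------- protein rigid moves
        elif kind == 2 or kind == 3 or kind == 4:
            i = targets[m]
            cx = pc[i, 0]
            cy = pc[i, 1]
            cz = pc[i, 2]
            dflex = 0.0
            theta_new = theta[i]
            if kind == 2:  # translate
                amp = mp[1]
                cx += amp * (2.0 * u[m, 0] - 1.0)
                cy += amp * (2.0 * u[m, 1] - 1.0)
                cz = (cz + amp * (2.0 * u[m, 2] - 1.0)) % L
                # lateral cage: stand-in for a finite lateral cell, keeps
                # detached proteins within re-binding range
                if cx * cx + cy * cy > mp[7] * mp[7]:
                    continue
                for s in range(5):
                    for k in range(3):
                        off_t[s, k] = off[i, s, k]
                        bdir_t[s, k] = bdir[i, s, k]
                uacc = u[m, 3]
            elif kind == 3:  # rotate about a random axis through the centre
                zax = 2.0 * u[m, 0] - 1.0
                phi_ = 2.0 * np.pi * u[m, 1]
                sxy = np.sqrt(max(0.0, 1.0 - zax * zax))
                _rodrigues(sxy * np.cos(phi_), sxy * np.sin(phi_), zax,
                           mp[2] * (2.0 * u[m, 2] - 1.0), Rd)
                for s in range(5):
                    for k in range(3):
                        off_t[s, k] = (Rd[k, 0] * off[i, s, 0]
                                       + Rd[k, 1] * off[i, s, 1]
                                       + Rd[k, 2] * off[i, s, 2])
                        bdir_t[s, k] = (Rd[k, 0] * bdir[i, s, 0]
                                        + Rd[k, 1] * bdir[i, s, 1]
                                        + Rd[k, 2] * bdir[i, s, 2])
                uacc = u[m, 3]
            else:  # wing (hinge) move
                theta_new = theta[i] + mp[3] * (2.0 * u[m, 0] - 1.0)
                if theta_new <= 0.0 or theta_new >= np.pi:
                    continue
                protein_local(Rpr, alpha, theta_eq, theta_new, off_l, bdir_l)
                for s in range(5):
                    for k in range(3):
                        off_t[s, k] = (rot[i, k, 0] * off_l[s, 0]
                                       + rot[i, k, 1] * off_l[s, 1]
                                       + rot[i, k, 2] * off_l[s, 2])
                        bdir_t[s, k] = (rot[i, k, 0] * bdir_l[s, 0]
                                        + rot[i, k, 1] * bdir_l[s, 1]
                                        + rot[i, k, 2] * bdir_l[s, 2])
                dflex = 0.5 * kflex * ((theta_new - theta_eq) ** 2
                                       - (theta[i] - theta_eq) ** 2)
                uacc = u[m, 1]
            if _protein_vs_others(pc, off, i, cx, cy, cz, off_t, dcol, L):
                continue
            u_new, ok = _protein_adh(pos, L, cx, cy, cz, off_t, bdir_t,
                                     eps, cos_thpr, rcut, dmin)
            if not ok:
                continue
            u_old, _ = _protein_adh(pos, L, pc[i, 0], pc[i, 1], pc[i, 2],
                                    off[i], bdir[i], eps, cos_thpr, rcut, dmin)
            du = (u_new - u_old) + dflex
            if du <= 0.0 or uacc < np.exp(-du):
                pc[i, 0] = cx
                pc[i, 1] = cy
                pc[i, 2] = cz
                for s in range(5):
                    for k in range(3):
                        off[i, s, k] = off_t[s, k]
                        bdir[i, s, k] = bdir_t[s, k]
                if kind == 3:
                    for r_ in range(3):
                        for k in range(3):
                            n1[k] = (Rd[r_, 0] * rot[i, 0, k]
                                     + Rd[r_, 1] * rot[i, 1, k]
                                     + Rd[r_, 2] * rot[i, 2, k])
                        for k in range(3):
                            rot[i, r_, k] = n1[k]
                theta[i] = theta_new
                en[2] += u_new - u_old
                en[3] += dflex
                acc[kind, 1] += 1

        # ------------------------------------------------------ box rescale
        else:
            lam = 1.0 + mp[4] * (2.0 * u[m, 0] - 1.0)
            L_new = L * lam
            if L_new < mp[5] or L_new > mp[6]:
                continue
            pos2 = pos.copy()
            pc2 = pc.copy()
            for v in range(V):
                pos2[v, 2] = pos[v, 2] * lam
            for i in range(NP):
                pc2[i, 2] = pc[i, 2] * lam
            if not check_tethers(pos2, edges, L_new, lmin, lmax):
                continue
            # hard core via a temporary cell list at the new box length
            gi2 = gi.copy()
            gf2 = gf.copy()
            gi2[2] = max(3, int(L_new))
            gf2[3] = L_new / gi2[2]
            head2 = np.full(gi2[0] * gi2[1] * gi2[2], -1, dtype=np.int64)
            nxt2 = np.empty(V, dtype=np.int64)
            prv2 = np.empty(V, dtype=np.int64)
            bc2 = np.empty(V, dtype=np.int64)
            build_cells(pos2, L_new, gf2, gi2, head2, nxt2, prv2, bc2)
            if not _cells_ok(pos2, L_new, gf2, gi2, head2, nxt2, bc2, sig):
                continue
            if not check_sphere_sphere(pc2, off, dcol, L_new):
                continue
            u_adh, ok = full_adhesion(pos2, L_new, pc2, off, bdir,
                                      eps, cos_thpr, rcut, dmin)
            if not ok:
                continue
            u_bend = kappa * full_bend(pos2, tri, edge_tri, L_new)
            a_new = full_area(pos2, tri, L_new)
            u_cp = full_cp(pos2, L_new, kcp, Req, flo, fhi)
            du = (u_bend - en[0]) + gamma * (a_new - en[1]) \
                + (u_adh - en[2]) + (u_cp - en[4])
            logw = (V + NP) * np.log(lam)
            x = -du + logw
            if x >= 0.0 or u[m, 1] < np.exp(x):
                for v in range(V):
                    pos[v, 2] = pos2[v, 2]
                for i in range(NP):
                    pc[i, 2] = pc2[i, 2]
                box[0] = L_new
                L = L_new
                gi[2] = gi2[2]
                gf[3] = gf2[3]
                build_cells(pos, L, gf, gi, head, nxt, prv, bead_cell)
                en[0] = u_bend
                en[1] = a_new
                en[2] = u_adh
                en[4] = u_cp
                acc[kind, 1] += 1
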