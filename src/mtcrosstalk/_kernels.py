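"""Compiled (numba) inner-loop kernels for the simulation engine.

Layout conventions:

* membrane / nucleus positions: ``(n, 2)`` float64 rings;
* microtubules: padded ``(N, maxB, 2)`` array with per-filament bead count
  ``mt_n``; bead 0 is the minus end pinned at the centrosome;
* steric pairs are kept in preallocated Verlet lists with a skin; lists are
  rebuilt when any bead has moved more than ``skin/2`` since the last
  rebuild.  A bead added at a growing plus end is patched into the lists
  immediately (with an enlarged search radius) and stamped with a per-bead
  "era" counter so that entries referring to removed beads are ignored.

Scalar model parameters are passed packed in a float64 vector ``PF`` (see
the ``PF_*`` index constants) to keep kernel signatures manageable.

The readable reference implementations of the same physics live in
:mod:`mtcrosstalk.mechanics`, :mod:`mtcrosstalk.crosstalk`,
:mod:`mtcrosstalk.mt_dynamics` and :mod:`mtcrosstalk.motors`; the test
suite checks the two paths against each other.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

# WCA cutoff factor 2^(1/6)
RC = 2.0 ** (1.0 / 6.0)

# status codes returned by advance_chunk
OK = 0
ERR_DISPLACEMENT = 1
ERR_NONFINITE = 2
ERR_PAIR_OVERFLOW = 3

# ---- packed float parameter indices -------------------------------------
PF_DT = 0
PF_SIGMA = 1
PF_EPS = 2
PF_FCAP = 3
PF_KS_MEM = 4
PF_KAPPA_MEM = 5
PF_L0_MEM = 6
PF_THETA0_MEM = 7
PF_KS_NUC = 8
PF_KAPPA_NUC = 9
PF_L0_NUC = 10
PF_THETA0_NUC = 11
PF_KS_MT = 12
PF_KAPPA_MT = 13
PF_K_COUPLE = 14
PF_REST_COUPLE = 15
PF_V_PROT0 = 16
PF_F_CONTR0 = 17
PF_R_SIGNAL = 18
PF_GAMMA_MEM = 19
PF_GAMMA_NUC = 20
PF_GAMMA_CEN = 21
PF_GAMMA_MT = 22
PF_P_CAT = 23
PF_P_RES = 24
PF_VG = 25
PF_VS = 26
PF_P_ON = 27
PF_P_OFF = 28
PF_V_MOTOR = 29
PF_K_MOTOR = 30
PF_R_CAPTURE = 31
PF_F_STALL = 32
PF_V_CHEMO = 33
PF_CHEMO_X = 34
PF_CHEMO_Y = 35
PF_SKIN = 36
PF_MAX_DISP = 37
PF_LEN_CAP = 38
PF_SIG_DECAY = 39
PF_N_SUB = 40
PF_K_AREA_NUC = 41
PF_A0_NUC = 42
PF_K_AREA_MEM = 43
PF_A0_MEM = 44
PF_FCAP_SURF = 45
PF_N = 46  # size of the packed vector

GROW = 1
SHRINK = 0


# ==========================================================================
# elementary force kernels
# ==========================================================================

@njit(cache=True, fastmath=True)
def _wca_mag(d, sigma, eps, fcap):
    """Repulsive WCA force magnitude at center distance d (0 beyond cutoff)."""
    if d >= RC * sigma or d <= 0.0:
        return 0.0
    s2 = (sigma / d) * (sigma / d)
    s6 = s2 * s2 * s2
    mag = 24.0 * eps * (2.0 * s6 * s6 - s6) / d
    if mag > fcap:
        mag = fcap
    return mag


@njit(cache=True, fastmath=True)
def stretch_ring_kernel(pos, ks, l0, f):
    n = pos.shape[0]
    for i in range(n):
        j = i + 1
        if j == n:
            j = 0
        dx = pos[j, 0] - pos[i, 0]
        dy = pos[j, 1] - pos[i, 1]
        r = math.sqrt(dx * dx + dy * dy)
        if r < 1e-12:
            continue
        c = ks * (r - l0) / r
        f[i, 0] += c * dx
        f[i, 1] += c * dy
        f[j, 0] -= c * dx
        f[j, 1] -= c * dy


@njit(cache=True, fastmath=True)
def stretch_chain_kernel(pos, n, ks, l0, f):
    for i in range(n - 1):
        dx = pos[i + 1, 0] - pos[i, 0]
        dy = pos[i + 1, 1] - pos[i, 1]
        r = math.sqrt(dx * dx + dy * dy)
        if r < 1e-12:
            continue
        c = ks * (r - l0) / r
        f[i, 0] += c * dx
        f[i, 1] += c * dy
        f[i + 1, 0] -= c * dx
        f[i + 1, 1] -= c * dy


@njit(cache=True, fastmath=True)
def _bend_vertex(pos, im1, i, ip1, w0, theta0, f):
    """Add bending forces of one vertex; w0 = kappa / l0."""
    ax = pos[i, 0] - pos[im1, 0]
    ay = pos[i, 1] - pos[im1, 1]
    bx = pos[ip1, 0] - pos[i, 0]
    by = pos[ip1, 1] - pos[i, 1]
    la2 = ax * ax + ay * ay
    lb2 = bx * bx + by * by
    if la2 < 1e-24 or lb2 < 1e-24:
        return
    cross = ax * by - ay * bx
    dot = ax * bx + ay * by
    # arctan series for the (dominant) small-angle case; atan2 fallback
    if dot > 0.0 and abs(cross) < 0.3 * dot:
        x = cross / dot
        x2 = x * x
        theta = x * (1.0 - x2 / 3.0 + x2 * x2 / 5.0 - x2 * x2 * x2 / 7.0)
    else:
        theta = math.atan2(cross, dot)
    w = w0 * (theta - theta0)
    gax = -ay / la2
    gay = ax / la2
    gbx = -by / lb2
    gby = bx / lb2
    f[im1, 0] -= w * gax
    f[im1, 1] -= w * gay
    f[ip1, 0] -= w * gbx
    f[ip1, 1] -= w * gby
    f[i, 0] += w * (gax + gbx)
    f[i, 1] += w * (gay + gby)


@njit(cache=True, fastmath=True)
def bend_ring_kernel(pos, kappa, l0, theta0, f):
    n = pos.shape[0]
    w0 = kappa / l0
    for i in range(n):
        im1 = i - 1 if i > 0 else n - 1
        ip1 = i + 1 if i < n - 1 else 0
        _bend_vertex(pos, im1, i, ip1, w0, theta0, f)


@njit(cache=True, fastmath=True)
def bend_chain_kernel(pos, n, kappa, l0, f):
    w0 = kappa / l0
    for i in range(1, n - 1):
        _bend_vertex(pos, i - 1, i, i + 1, w0, 0.0, f)


@njit(cache=True, fastmath=True)
def _seg_dist(px, py, ax, ay, bx, by):
    """Distance from point p to segment ab and the closest-point direction."""
    vx = bx - ax
    vy = by - ay
    wx = px - ax
    wy = py - ay
    L2 = vx * vx + vy * vy
    if L2 < 1e-24:
        t = 0.0
    else:
        t = (wx * vx + wy * vy) / L2
        if t < 0.0:
            t = 0.0
        elif t > 1.0:
            t = 1.0
    qx = ax + t * vx
    qy = ay + t * vy
    dx = px - qx
    dy = py - qy
    return math.sqrt(dx * dx + dy * dy), dx, dy


@njit(cache=True, fastmath=True)
def _min_clearances(x, y, mem, nuc, obs, segs):
    """Nearest membrane/nucleus bead distance and nearest surface gap."""
    dmin = 1e30
    for i in range(mem.shape[0]):
        dx = x - mem[i, 0]
        dy = y - mem[i, 1]
        d2 = dx * dx + dy * dy
        if d2 < dmin:
            dmin = d2
    for j in range(nuc.shape[0]):
        dx = x - nuc[j, 0]
        dy = y - nuc[j, 1]
        d2 = dx * dx + dy * dy
        if d2 < dmin:
            dmin = d2
    gmin = 1e30
    for k in range(obs.shape[0]):
        dx = x - obs[k, 0]
        dy = y - obs[k, 1]
        g = math.sqrt(dx * dx + dy * dy) - obs[k, 2]
        if g < gmin:
            gmin = g
    for k in range(segs.shape[0]):
        d, _, _ = _seg_dist(x, y, segs[k, 0], segs[k, 1],
                            segs[k, 2], segs[k, 3])
        g = d - segs[k, 4]
        if g < gmin:
            gmin = g
    return math.sqrt(dmin), gmin


@njit(cache=True, fastmath=True)
def placement_blocked(x, y, tipx, tipy, mem, nuc, obs, segs, sigma):
    """True if a new plus-end bead at (x, y) would press deeper into the
    membrane, nucleus, an obstacle or a wall than the current tip."""
    d_new, g_new = _min_clearances(x, y, mem, nuc, obs, segs)
    if d_new < 0.8 * sigma or g_new < 0.1 * sigma:
        d_tip, g_tip = _min_clearances(tipx, tipy, mem, nuc, obs, segs)
        if d_new < 0.8 * sigma and d_new < d_tip:
            return True
        if g_new < 0.1 * sigma and g_new < g_tip:
            return True
    return False


@njit(cache=True, fastmath=True)
def _contact_normal(x, y, mem, nuc, obs, segs):
    """Unit vector pointing away from the nearest bead or surface."""
    best = 1e30
    nx = 0.0
    ny = 1.0
    for i in range(mem.shape[0]):
        dx = x - mem[i, 0]
        dy = y - mem[i, 1]
        d2 = dx * dx + dy * dy
        if d2 < best:
            best = d2
            nx = dx
            ny = dy
    for j in range(nuc.shape[0]):
        dx = x - nuc[j, 0]
        dy = y - nuc[j, 1]
        d2 = dx * dx + dy * dy
        if d2 < best:
            best = d2
            nx = dx
            ny = dy
    best = math.sqrt(best)
    for k in range(obs.shape[0]):
        dx = x - obs[k, 0]
        dy = y - obs[k, 1]
        d = math.sqrt(dx * dx + dy * dy)
        if d - obs[k, 2] < best and d > 1e-12:
            best = d - obs[k, 2]
            nx = dx / d
            ny = dy / d
    for k in range(segs.shape[0]):
        d, dx, dy = _seg_dist(x, y, segs[k, 0], segs[k, 1],
                              segs[k, 2], segs[k, 3])
        if d - segs[k, 4] < best and d > 1e-12:
            best = d - segs[k, 4]
            nx = dx / d
            ny = dy / d
    L = math.sqrt(nx * nx + ny * ny)
    if L < 1e-12:
        return 0.0, 1.0
    return nx / L, ny / L


@njit(cache=True, fastmath=True)
def deflect_growth(tipx, tipy, tx, ty, mem, nuc, obs, segs, sigma):
    """Candidate position for a new plus-end bead with tip gliding.

    The straight continuation along the tangent is used when it does not
    press deeper into a surface than the current tip; otherwise the growth
    direction is projected onto the local surface tangent (gliding along
    membranes, walls and obstacles).  Head-on contact stalls: returns
    (nan, nan).
    """
    nx_ = tipx + sigma * tx
    ny_ = tipy + sigma * ty
    if not placement_blocked(nx_, ny_, tipx, tipy, mem, nuc, obs, segs,
                             sigma):
        return nx_, ny_
    cnx, cny = _contact_normal(nx_, ny_, mem, nuc, obs, segs)
    dot = tx * cnx + ty * cny
    px = tx - dot * cnx
    py = ty - dot * cny
    L = math.sqrt(px * px + py * py)
    if L < 0.2:
        return np.nan, np.nan   # head-on: polymerization stalls
    px /= L
    py /= L
    nx_ = tipx + sigma * px
    ny_ = tipy + sigma * py
    if placement_blocked(nx_, ny_, tipx, tipy, mem, nuc, obs, segs, sigma):
        return np.nan, np.nan
    return nx_, ny_


# ==========================================================================
# pair-list construction
# ==========================================================================

@njit(cache=True)
def build_pairs_kernel(mem, nuc, mt_pos, mt_n, era, obs, segs,
                       r_bb, r_tm, r_sb,
                       mm_i, mm_j, mn_i, mn_j,
                       tm_m, tm_b, tm_e, tm_t,
                       tn_m, tn_b, tn_e, tn_t,
                       sb_type, sb_i1, sb_i2, sb_e, sb_kind, sb_k,
                       cnt):
    """Rebuild all Verlet pair lists.  Returns 0, or -1 on overflow.

    ``r_bb``: bead-bead list radius; ``r_tm``: MT-bead to membrane/nucleus
    radius (covers both the WCA cutoff and the motor capture radius);
    ``r_sb``: surface-gap radius for obstacles and walls.
    """
    nm = mem.shape[0]
    nn = nuc.shape[0]
    N = mt_pos.shape[0]
    no = obs.shape[0]
    ns = segs.shape[0]
    cap_mm = mm_i.shape[0]
    cap_mn = mn_i.shape[0]
    cap_tm = tm_m.shape[0]
    cap_tn = tn_m.shape[0]
    cap_sb = sb_type.shape[0]

    # membrane-membrane (non-neighbor self avoidance)
    c = 0
    r2 = r_bb * r_bb
    for i in range(nm):
        for j in range(i + 2, nm):
            if i == 0 and j == nm - 1:
                continue
            dx = mem[i, 0] - mem[j, 0]
            dy = mem[i, 1] - mem[j, 1]
            if dx * dx + dy * dy < r2:
                if c >= cap_mm:
                    return -1
                mm_i[c] = i
                mm_j[c] = j
                c += 1
    cnt[0] = c

    # membrane-nucleus
    c = 0
    for i in range(nm):
        for j in range(nn):
            dx = mem[i, 0] - nuc[j, 0]
            dy = mem[i, 1] - nuc[j, 1]
            if dx * dx + dy * dy < r2:
                if c >= cap_mn:
                    return -1
                mn_i[c] = i
                mn_j[c] = j
                c += 1
    cnt[1] = c

    # grid over membrane + nucleus beads with cell size r_tm
    xmin = mem[0, 0]
    xmax = mem[0, 0]
    ymin = mem[0, 1]
    ymax = mem[0, 1]
    for i in range(nm):
        if mem[i, 0] < xmin:
            xmin = mem[i, 0]
        if mem[i, 0] > xmax:
            xmax = mem[i, 0]
        if mem[i, 1] < ymin:
            ymin = mem[i, 1]
        if mem[i, 1] > ymax:
            ymax = mem[i, 1]
    for j in range(nn):
        if nuc[j, 0] < xmin:
            xmin = nuc[j, 0]
        if nuc[j, 0] > xmax:
            xmax = nuc[j, 0]
        if nuc[j, 1] < ymin:
            ymin = nuc[j, 1]
        if nuc[j, 1] > ymax:
            ymax = nuc[j, 1]
    cell = r_tm
    ncx = int((xmax - xmin) / cell) + 1
    ncy = int((ymax - ymin) / cell) + 1
    ncell = ncx * ncy
    head = np.full(ncell, -1, dtype=np.int64)
    nxt = np.full(nm + nn, -1, dtype=np.int64)
    for p in range(nm + nn):
        if p < nm:
            x = mem[p, 0]
            y = mem[p, 1]
        else:
            x = nuc[p - nm, 0]
            y = nuc[p - nm, 1]
        ix = int((x - xmin) / cell)
        iy = int((y - ymin) / cell)
        idx = iy * ncx + ix
        nxt[p] = head[idx]
        head[idx] = p

    ctm = 0
    ctn = 0
    rtm2 = r_tm * r_tm
    for m in range(N):
        nb = mt_n[m]
        for b in range(nb):
            x = mt_pos[m, b, 0]
            y = mt_pos[m, b, 1]
            ix = int((x - xmin) / cell)
            iy = int((y - ymin) / cell)
            for gy in range(iy - 1, iy + 2):
                if gy < 0 or gy >= ncy:
                    continue
                for gx in range(ix - 1, ix + 2):
                    if gx < 0 or gx >= ncx:
                        continue
                    p = head[gy * ncx + gx]
                    while p >= 0:
                        if p < nm:
                            dx = x - mem[p, 0]
                            dy = y - mem[p, 1]
                            if dx * dx + dy * dy < rtm2:
                                if ctm >= cap_tm:
                                    return -1
                                tm_m[ctm] = m
                                tm_b[ctm] = b
                                tm_e[ctm] = era[m, b]
                                tm_t[ctm] = p
                                ctm += 1
                        else:
                            dx = x - nuc[p - nm, 0]
                            dy = y - nuc[p - nm, 1]
                            if dx * dx + dy * dy < rtm2:
                                if ctn >= cap_tn:
                                    return -1
                                tn_m[ctn] = m
                                tn_b[ctn] = b
                                tn_e[ctn] = era[m, b]
                                tn_t[ctn] = p - nm
                                ctn += 1
                        p = nxt[p]
    cnt[2] = ctm
    cnt[3] = ctn

    # surfaces (obstacles kind 0, walls kind 1) vs every bead
    csb = 0
    if no > 0 or ns > 0:
        # membrane (type 0) and nucleus (type 1) beads
        for t in range(2):
            npts = nm if t == 0 else nn
            for i in range(npts):
                if t == 0:
                    x = mem[i, 0]
                    y = mem[i, 1]
                else:
                    x = nuc[i, 0]
                    y = nuc[i, 1]
                for k in range(no):
                    dx = x - obs[k, 0]
                    dy = y - obs[k, 1]
                    g = math.sqrt(dx * dx + dy * dy) - obs[k, 2]
                    if g < r_sb:
                        if csb >= cap_sb:
                            return -1
                        sb_type[csb] = t
                        sb_i1[csb] = i
                        sb_i2[csb] = 0
                        sb_e[csb] = 0
                        sb_kind[csb] = 0
                        sb_k[csb] = k
                        csb += 1
                for k in range(ns):
                    d, _, _ = _seg_dist(x, y, segs[k, 0], segs[k, 1],
                                        segs[k, 2], segs[k, 3])
                    if d - segs[k, 4] < r_sb:
                        if csb >= cap_sb:
                            return -1
                        sb_type[csb] = t
                        sb_i1[csb] = i
                        sb_i2[csb] = 0
                        sb_e[csb] = 0
                        sb_kind[csb] = 1
                        sb_k[csb] = k
                        csb += 1
        # microtubule beads (type 2), minus-end bead excluded
        for m in range(N):
            nb = mt_n[m]
            for b in range(1, nb):
                x = mt_pos[m, b, 0]
                y = mt_pos[m, b, 1]
                for k in range(no):
                    dx = x - obs[k, 0]
                    dy = y - obs[k, 1]
                    g = math.sqrt(dx * dx + dy * dy) - obs[k, 2]
                    if g < r_sb:
                        if csb >= cap_sb:
                            return -1
                        sb_type[csb] = 2
                        sb_i1[csb] = m
                        sb_i2[csb] = b
                        sb_e[csb] = era[m, b]
                        sb_kind[csb] = 0
                        sb_k[csb] = k
                        csb += 1
                for k in range(ns):
                    d, _, _ = _seg_dist(x, y, segs[k, 0], segs[k, 1],
                                        segs[k, 2], segs[k, 3])
                    if d - segs[k, 4] < r_sb:
                        if csb >= cap_sb:
                            return -1
                        sb_type[csb] = 2
                        sb_i1[csb] = m
                        sb_i2[csb] = b
                        sb_e[csb] = era[m, b]
                        sb_kind[csb] = 1
                        sb_k[csb] = k
                        csb += 1
    cnt[4] = csb
    return 0


@njit(cache=True)
def patch_new_bead_kernel(m, b, mem, nuc, mt_pos, era, obs, segs,
                          r_tm, r_sb,
                          tm_m, tm_b, tm_e, tm_t,
                          tn_m, tn_b, tn_e, tn_t,
                          sb_type, sb_i1, sb_i2, sb_e, sb_kind, sb_k,
                          cnt):
    """Append list entries for a freshly added plus-end bead.

    Search radii are enlarged by the caller (1.5 x skin) so the Verlet
    guarantee holds against beads that have drifted since the last rebuild.
    Returns 0, or -1 on overflow (caller then forces a full rebuild).
    """
    x = mt_pos[m, b, 0]
    y = mt_pos[m, b, 1]
    e = era[m, b]
    nm = mem.shape[0]
    nn = nuc.shape[0]
    rtm2 = r_tm * r_tm
    ctm = cnt[2]
    ctn = cnt[3]
    csb = cnt[4]
    for p in range(nm):
        dx = x - mem[p, 0]
        dy = y - mem[p, 1]
        if dx * dx + dy * dy < rtm2:
            if ctm >= tm_m.shape[0]:
                return -1
            tm_m[ctm] = m
            tm_b[ctm] = b
            tm_e[ctm] = e
            tm_t[ctm] = p
            ctm += 1
    for p in range(nn):
        dx = x - nuc[p, 0]
        dy = y - nuc[p, 1]
        if dx * dx + dy * dy < rtm2:
            if ctn >= tn_m.shape[0]:
                return -1
            tn_m[ctn] = m
            tn_b[ctn] = b
            tn_e[ctn] = e
            tn_t[ctn] = p
            ctn += 1
    for k in range(obs.shape[0]):
        dx = x - obs[k, 0]
        dy = y - obs[k, 1]
        g = math.sqrt(dx * dx + dy * dy) - obs[k, 2]
        if g < r_sb:
            if csb >= sb_type.shape[0]:
                return -1
            sb_type[csb] = 2
            sb_i1[csb] = m
            sb_i2[csb] = b
            sb_e[csb] = e
            sb_kind[csb] = 0
            sb_k[csb] = k
            csb += 1
    for k in range(segs.shape[0]):
        d, _, _ = _seg_dist(x, y, segs[k, 0], segs[k, 1],
                            segs[k, 2], segs[k, 3])
        if d - segs[k, 4] < r_sb:
            if csb >= sb_type.shape[0]:
                return -1
            sb_type[csb] = 2
            sb_i1[csb] = m
            sb_i2[csb] = b
            sb_e[csb] = e
            sb_kind[csb] = 1
            sb_k[csb] = k
            csb += 1
    cnt[2] = ctm
    cnt[3] = ctn
    cnt[4] = csb
    return 0


# ==========================================================================
# steric evaluation
# ==========================================================================

@njit(cache=True, fastmath=True)
def eval_steric_kernel(mem, nuc, cen, mt_pos, mt_n, era, obs, segs,
                       sigma, eps, fcap, fcap_surf,
                       mm_i, mm_j, mn_i, mn_j,
                       tm_m, tm_b, tm_e, tm_t,
                       tn_m, tn_b, tn_e, tn_t,
                       sb_type, sb_i1, sb_i2, sb_e, sb_kind, sb_k,
                       cnt, f_mem, f_nuc, f_mt, f_cen):
    """Accumulate all WCA forces from the current pair lists."""
    for c in range(cnt[0]):
        i = mm_i[c]
        j = mm_j[c]
        dx = mem[i, 0] - mem[j, 0]
        dy = mem[i, 1] - mem[j, 1]
        d = math.sqrt(dx * dx + dy * dy)
        mag = _wca_mag(d, sigma, eps, fcap)
        if mag > 0.0:
            fx = mag * dx / d
            fy = mag * dy / d
            f_mem[i, 0] += fx
            f_mem[i, 1] += fy
            f_mem[j, 0] -= fx
            f_mem[j, 1] -= fy
    for c in range(cnt[1]):
        i = mn_i[c]
        j = mn_j[c]
        dx = mem[i, 0] - nuc[j, 0]
        dy = mem[i, 1] - nuc[j, 1]
        d = math.sqrt(dx * dx + dy * dy)
        mag = _wca_mag(d, sigma, eps, fcap)
        if mag > 0.0:
            fx = mag * dx / d
            fy = mag * dy / d
            f_mem[i, 0] += fx
            f_mem[i, 1] += fy
            f_nuc[j, 0] -= fx
            f_nuc[j, 1] -= fy
    for c in range(cnt[2]):
        m = tm_m[c]
        b = tm_b[c]
        if b == 0 or b >= mt_n[m] or era[m, b] != tm_e[c]:
            continue
        i = tm_t[c]
        dx = mt_pos[m, b, 0] - mem[i, 0]
        dy = mt_pos[m, b, 1] - mem[i, 1]
        d = math.sqrt(dx * dx + dy * dy)
        mag = _wca_mag(d, sigma, eps, fcap)
        if mag > 0.0:
            fx = mag * dx / d
            fy = mag * dy / d
            f_mt[m, b, 0] += fx
            f_mt[m, b, 1] += fy
            f_mem[i, 0] -= fx
            f_mem[i, 1] -= fy
    for c in range(cnt[3]):
        m = tn_m[c]
        b = tn_b[c]
        if b == 0 or b >= mt_n[m] or era[m, b] != tn_e[c]:
            continue
        j = tn_t[c]
        dx = mt_pos[m, b, 0] - nuc[j, 0]
        dy = mt_pos[m, b, 1] - nuc[j, 1]
        d = math.sqrt(dx * dx + dy * dy)
        mag = _wca_mag(d, sigma, eps, fcap)
        if mag > 0.0:
            fx = mag * dx / d
            fy = mag * dy / d
            f_mt[m, b, 0] += fx
            f_mt[m, b, 1] += fy
            f_nuc[j, 0] -= fx
            f_nuc[j, 1] -= fy
    # obstacles / walls: WCA on the surface gap, onset at the surface
    for c in range(cnt[4]):
        t = sb_type[c]
        if t == 0:
            x = mem[sb_i1[c], 0]
            y = mem[sb_i1[c], 1]
        elif t == 1:
            x = nuc[sb_i1[c], 0]
            y = nuc[sb_i1[c], 1]
        else:
            m = sb_i1[c]
            b = sb_i2[c]
            if b == 0 or b >= mt_n[m] or era[m, b] != sb_e[c]:
                continue
            x = mt_pos[m, b, 0]
            y = mt_pos[m, b, 1]
        if sb_kind[c] == 0:
            k = sb_k[c]
            dx = x - obs[k, 0]
            dy = y - obs[k, 1]
            d = math.sqrt(dx * dx + dy * dy)
            if d < 1e-12:
                continue
            g = d - obs[k, 2]
        else:
            k = sb_k[c]
            d, dx, dy = _seg_dist(x, y, segs[k, 0], segs[k, 1],
                                  segs[k, 2], segs[k, 3])
            if d < 1e-12:
                continue
            g = d - segs[k, 4]
        mag = _wca_mag(g + sigma, sigma, eps, fcap_surf)
        if g < 0.0:
            # linear depth penalty: rigid surfaces push back harder the
            # deeper a bead is driven below them
            mag = fcap_surf * (1.0 - 2.0 * g / sigma)
        if mag > 0.0:
            fx = mag * dx / d
            fy = mag * dy / d
            if t == 0:
                f_mem[sb_i1[c], 0] += fx
                f_mem[sb_i1[c], 1] += fy
            elif t == 1:
                f_nuc[sb_i1[c], 0] += fx
                f_nuc[sb_i1[c], 1] += fy
            else:
                f_mt[sb_i1[c], sb_i2[c], 0] += fx
                f_mt[sb_i1[c], sb_i2[c], 1] += fy
    # centrosome <-> nucleus
    for j in range(nuc.shape[0]):
        dx = cen[0] - nuc[j, 0]
        dy = cen[1] - nuc[j, 1]
        d = math.sqrt(dx * dx + dy * dy)
        mag = _wca_mag(d, sigma, eps, fcap)
        if mag > 0.0:
            fx = mag * dx / d
            fy = mag * dy / d
            f_cen[0] += fx
            f_cen[1] += fy
            f_nuc[j, 0] -= fx
            f_nuc[j, 1] -= fy


# ==========================================================================
# tip signals and membrane normals
# ==========================================================================

@njit(cache=True, fastmath=True)
def tip_signal_kernel(mem, mt_pos, mt_n, mt_state, r_signal, ng, nsh):
    """Count growing / shrinking plus-end tips within r_signal of each
    membrane bead (a tip near several beads is counted by each)."""
    nm = mem.shape[0]
    for i in range(nm):
        ng[i] = 0.0
        nsh[i] = 0.0
    r2 = r_signal * r_signal
    for m in range(mt_pos.shape[0]):
        tb = mt_n[m] - 1
        x = mt_pos[m, tb, 0]
        y = mt_pos[m, tb, 1]
        grow = mt_state[m] == GROW
        for i in range(nm):
            dx = x - mem[i, 0]
            dy = y - mem[i, 1]
            if dx * dx + dy * dy < r2:
                if grow:
                    ng[i] += 1.0
                else:
                    nsh[i] += 1.0


@njit(cache=True, fastmath=True)
def outward_normals_kernel(mem, normals):
    """Outward unit normals from the local tangent (neighbors i-1, i+1),
    oriented by the polygon winding; degenerate tangents copy the previous
    valid normal."""
    n = mem.shape[0]
    area2 = 0.0
    for i in range(n):
        j = i + 1 if i < n - 1 else 0
        area2 += mem[i, 0] * mem[j, 1] - mem[j, 0] * mem[i, 1]
    sgn = 1.0 if area2 > 0.0 else -1.0
    for i in range(n):
        im1 = i - 1 if i > 0 else n - 1
        ip1 = i + 1 if i < n - 1 else 0
        tx = mem[ip1, 0] - mem[im1, 0]
        ty = mem[ip1, 1] - mem[im1, 1]
        L = math.sqrt(tx * tx + ty * ty)
        if L < 1e-12:
            normals[i, 0] = normals[i - 1, 0]
            normals[i, 1] = normals[i - 1, 1]
        else:
            normals[i, 0] = sgn * ty / L
            normals[i, 1] = -sgn * tx / L


# ==========================================================================
# the chunked inner loop
# ==========================================================================

@njit(cache=True)
def advance_chunk(
    # state
    mem, nuc, cen, mt_pos, mt_n, mt_state, mt_partial, mt_dir, era,
    # motors
    a_loop, a_bead, a_bound, a_mt, a_arc, mem_aid, nuc_aid,
    # environment
    obs, segs,
    # coupling map
    cpl,
    # pair lists + refs
    mm_i, mm_j, mn_i, mn_j,
    tm_m, tm_b, tm_e, tm_t, tn_m, tn_b, tn_e, tn_t,
    sb_type, sb_i1, sb_i2, sb_e, sb_kind, sb_k, cnt,
    ref_mem, ref_nuc, ref_mt,
    # random numbers for the chunk
    u_sw, u_th, u_att, u_det,
    # signal traces (per membrane bead)
    sg, ss, use_trace,
    # scratch
    f_mem, f_nuc, f_mt, f_cen, e_mem, e_nuc, e_mt, vact, normals, ng, nsh,
    best_d2, best_m, best_b,
    # packed parameters, rebuild request
    PF, force_rebuild,
):
    """Advance the full state by ``u_sw.shape[0]`` steps.

    Per step: dynamic-instability switching -> tip advance (with pair-list
    patching) -> tip signals -> passive forces -> steric forces -> dynein
    attach/step -> crosstalk contraction + protrusion -> chemotactic bias ->
    forward Euler update -> minus-end re-pinning.

    Returns (status, steps_completed).
    """
    n_steps = u_sw.shape[0]
    nm = mem.shape[0]
    nn = nuc.shape[0]
    N = mt_pos.shape[0]
    A = a_bead.shape[0]
    maxB = mt_pos.shape[1]

    dt = PF[PF_DT]
    sigma = PF[PF_SIGMA]
    eps = PF[PF_EPS]
    fcap = PF[PF_FCAP]
    skin = PF[PF_SKIN]
    r_bb = RC * sigma + skin
    r_cap = PF[PF_R_CAPTURE]
    r_tm = max(RC * sigma, r_cap) + skin
    r_sb = (RC - 1.0) * sigma + skin
    half_skin2 = 0.25 * skin * skin
    max_disp2 = PF[PF_MAX_DISP] * PF[PF_MAX_DISP]
    len_cap = PF[PF_LEN_CAP]
    need_rebuild = force_rebuild != 0

    for s in range(n_steps):
        # ---- dynamic instability switching --------------------------------
        for m in range(N):
            if mt_state[m] == GROW:
                if u_sw[s, m] < PF[PF_P_CAT]:
                    mt_state[m] = SHRINK
            else:
                if u_sw[s, m] < PF[PF_P_RES]:
                    mt_state[m] = GROW

        # ---- plus-end advance ---------------------------------------------
        for m in range(N):
            if mt_state[m] == GROW:
                mt_partial[m] += PF[PF_VG] * dt
                if (mt_n[m] - 1) * sigma + mt_partial[m] > len_cap:
                    mt_state[m] = SHRINK  # length cap: forced catastrophe
                    continue
                while mt_partial[m] >= sigma:
                    nb = mt_n[m]
                    if nb >= maxB:
                        mt_state[m] = SHRINK
                        break
                    if nb >= 2:
                        tx = mt_pos[m, nb - 1, 0] - mt_pos[m, nb - 2, 0]
                        ty = mt_pos[m, nb - 1, 1] - mt_pos[m, nb - 2, 1]
                        L = math.sqrt(tx * tx + ty * ty)
                        if L < 1e-12:
                            tx = mt_dir[m, 0]
                            ty = mt_dir[m, 1]
                        else:
                            tx /= L
                            ty /= L
                    else:
                        tx = mt_dir[m, 0]
                        ty = mt_dir[m, 1]
                    nx, ny = deflect_growth(
                        mt_pos[m, nb - 1, 0], mt_pos[m, nb - 1, 1], tx, ty,
                        mem, nuc, obs, segs, sigma)
                    if not math.isfinite(nx):
                        # head-on contact: polymerization stalls with the
                        # accumulator held at the addition threshold
                        mt_partial[m] = sigma
                        break
                    mt_pos[m, nb, 0] = nx
                    mt_pos[m, nb, 1] = ny
                    era[m, nb] += 1
                    ref_mt[m, nb, 0] = mt_pos[m, nb, 0]
                    ref_mt[m, nb, 1] = mt_pos[m, nb, 1]
                    mt_n[m] = nb + 1
                    mt_partial[m] -= sigma
                    if not need_rebuild:
                        st = patch_new_bead_kernel(
                            m, nb, mem, nuc, mt_pos, era, obs, segs,
                            r_tm + 0.5 * skin, r_sb + 0.5 * skin,
                            tm_m, tm_b, tm_e, tm_t,
                            tn_m, tn_b, tn_e, tn_t,
                            sb_type, sb_i1, sb_i2, sb_e, sb_kind, sb_k, cnt)
                        if st != 0:
                            need_rebuild = True
            else:
                mt_partial[m] -= PF[PF_VS] * dt
                while mt_partial[m] < 0.0:
                    if mt_n[m] > 1:
                        mt_n[m] -= 1
                        mt_partial[m] += sigma
                    else:
                        # re-nucleation with a fresh random direction
                        th = 2.0 * math.pi * u_th[s, m]
                        mt_dir[m, 0] = math.cos(th)
                        mt_dir[m, 1] = math.sin(th)
                        mt_state[m] = GROW
                        mt_partial[m] = 0.0
                        break

        # ---- tip signals --------------------------------------------------
        tip_signal_kernel(mem, mt_pos, mt_n, mt_state, PF[PF_R_SIGNAL],
                          ng, nsh)
        if use_trace:
            dec = PF[PF_SIG_DECAY]
            for i in range(nm):
                sg[i] = dec * sg[i] + (1.0 - dec) * ng[i]
                ss[i] = dec * ss[i] + (1.0 - dec) * nsh[i]
        else:
            for i in range(nm):
                sg[i] = ng[i]
                ss[i] = nsh[i]

        # ---- zero slow-force accumulators --------------------------------
        # f_* collect the slowly varying forces (steric, motors, crosstalk,
        # coupling); the stiff local elasticity (stretch + bend) is
        # sub-cycled in the integration stage below.
        for i in range(nm):
            f_mem[i, 0] = 0.0
            f_mem[i, 1] = 0.0
            vact[i, 0] = 0.0
            vact[i, 1] = 0.0
        for j in range(nn):
            f_nuc[j, 0] = 0.0
            f_nuc[j, 1] = 0.0
        for m in range(N):
            for b in range(mt_n[m]):
                f_mt[m, b, 0] = 0.0
                f_mt[m, b, 1] = 0.0
        f_cen[0] = 0.0
        f_cen[1] = 0.0

        # area pressure: restores the enclosed (signed) area of each ring
        ka = PF[PF_K_AREA_MEM]
        if ka > 0.0:
            area2 = 0.0
            for i in range(nm):
                i1 = i + 1 if i < nm - 1 else 0
                area2 += mem[i, 0] * mem[i1, 1] - mem[i1, 0] * mem[i, 1]
            coefa = ka * (PF[PF_A0_MEM] - 0.5 * area2) / PF[PF_A0_MEM]
            for i in range(nm):
                im = i - 1 if i > 0 else nm - 1
                ip = i + 1 if i < nm - 1 else 0
                f_mem[i, 0] += coefa * 0.5 * (mem[ip, 1] - mem[im, 1])
                f_mem[i, 1] += coefa * 0.5 * (mem[im, 0] - mem[ip, 0])
        ka = PF[PF_K_AREA_NUC]
        if ka > 0.0:
            area2 = 0.0
            for j in range(nn):
                j1 = j + 1 if j < nn - 1 else 0
                area2 += nuc[j, 0] * nuc[j1, 1] - nuc[j1, 0] * nuc[j, 1]
            coefa = ka * (PF[PF_A0_NUC] - 0.5 * area2) / PF[PF_A0_NUC]
            for j in range(nn):
                jm = j - 1 if j > 0 else nn - 1
                jp = j + 1 if j < nn - 1 else 0
                f_nuc[j, 0] += coefa * 0.5 * (nuc[jp, 1] - nuc[jm, 1])
                f_nuc[j, 1] += coefa * 0.5 * (nuc[jm, 0] - nuc[jp, 0])

        # nucleus-membrane elastic coupling (soft; once per step)
        kc = PF[PF_K_COUPLE]
        rc0 = PF[PF_REST_COUPLE]
        for j in range(nn):
            i = cpl[j]
            dx = mem[i, 0] - nuc[j, 0]
            dy = mem[i, 1] - nuc[j, 1]
            r = math.sqrt(dx * dx + dy * dy)
            if r > 1e-12:
                c = kc * (r - rc0) / r
                f_mem[i, 0] -= c * dx
                f_mem[i, 1] -= c * dy
                f_nuc[j, 0] += c * dx
                f_nuc[j, 1] += c * dy

        # ---- Verlet-list maintenance -------------------------------------
        if not need_rebuild:
            maxd2 = 0.0
            for i in range(nm):
                dx = mem[i, 0] - ref_mem[i, 0]
                dy = mem[i, 1] - ref_mem[i, 1]
                d2 = dx * dx + dy * dy
                if d2 > maxd2:
                    maxd2 = d2
            for j in range(nn):
                dx = nuc[j, 0] - ref_nuc[j, 0]
                dy = nuc[j, 1] - ref_nuc[j, 1]
                d2 = dx * dx + dy * dy
                if d2 > maxd2:
                    maxd2 = d2
            for m in range(N):
                for b in range(mt_n[m]):
                    dx = mt_pos[m, b, 0] - ref_mt[m, b, 0]
                    dy = mt_pos[m, b, 1] - ref_mt[m, b, 1]
                    d2 = dx * dx + dy * dy
                    if d2 > maxd2:
                        maxd2 = d2
            if maxd2 > half_skin2:
                need_rebuild = True
        if need_rebuild:
            st = build_pairs_kernel(mem, nuc, mt_pos, mt_n, era, obs, segs,
                                    r_bb, r_tm, r_sb,
                                    mm_i, mm_j, mn_i, mn_j,
                                    tm_m, tm_b, tm_e, tm_t,
                                    tn_m, tn_b, tn_e, tn_t,
                                    sb_type, sb_i1, sb_i2, sb_e, sb_kind,
                                    sb_k, cnt)
            if st != 0:
                return ERR_PAIR_OVERFLOW, s
            for i in range(nm):
                ref_mem[i, 0] = mem[i, 0]
                ref_mem[i, 1] = mem[i, 1]
            for j in range(nn):
                ref_nuc[j, 0] = nuc[j, 0]
                ref_nuc[j, 1] = nuc[j, 1]
            for m in range(N):
                for b in range(mt_n[m]):
                    ref_mt[m, b, 0] = mt_pos[m, b, 0]
                    ref_mt[m, b, 1] = mt_pos[m, b, 1]
            need_rebuild = False

        # ---- steric forces ------------------------------------------------
        eval_steric_kernel(mem, nuc, cen, mt_pos, mt_n, era, obs, segs,
                           sigma, eps, fcap, PF[PF_FCAP_SURF],
                           mm_i, mm_j, mn_i, mn_j,
                           tm_m, tm_b, tm_e, tm_t,
                           tn_m, tn_b, tn_e, tn_t,
                           sb_type, sb_i1, sb_i2, sb_e, sb_kind, sb_k,
                           cnt, f_mem, f_nuc, f_mt, f_cen)

        # ---- dynein: walk, pull, detach ----------------------------------
        for a in range(A):
            if not a_bound[a]:
                continue
            m = a_mt[a]
            Lm = (mt_n[m] - 1) * sigma + mt_partial[m]
            arc = a_arc[a] - PF[PF_V_MOTOR] * dt
            a_arc[a] = arc
            if arc <= 0.0:
                a_bound[a] = False  # reached the minus end: end dissociation
                a_mt[a] = -1
                a_arc[a] = 0.0
                continue
            if arc > Lm:
                a_bound[a] = False  # tip shrank past the motor
                a_mt[a] = -1
                continue
            if u_det[s, a] < PF[PF_P_OFF]:
                a_bound[a] = False
                a_mt[a] = -1
                continue
            if a_loop[a] == 0:
                ax = mem[a_bead[a], 0]
                ay = mem[a_bead[a], 1]
            else:
                ax = nuc[a_bead[a], 0]
                ay = nuc[a_bead[a], 1]
            if mt_n[m] < 2:
                px = mt_pos[m, 0, 0]
                py = mt_pos[m, 0, 1]
                j = 0
                frac = 0.0
            else:
                j = int(arc / sigma)
                if j > mt_n[m] - 2:
                    j = mt_n[m] - 2
                frac = arc / sigma - j
                if frac > 1.0:
                    frac = 1.0
                px = (1.0 - frac) * mt_pos[m, j, 0] + frac * mt_pos[m, j + 1, 0]
                py = (1.0 - frac) * mt_pos[m, j, 1] + frac * mt_pos[m, j + 1, 1]
            dx = px - ax
            dy = py - ay
            km = PF[PF_K_MOTOR]
            f2 = km * km * (dx * dx + dy * dy)
            if f2 > PF[PF_F_STALL] * PF[PF_F_STALL]:
                a_bound[a] = False  # stall-force detachment
                a_mt[a] = -1
                continue
            fx = km * dx
            fy = km * dy
            if a_loop[a] == 0:
                f_mem[a_bead[a], 0] += fx
                f_mem[a_bead[a], 1] += fy
            else:
                f_nuc[a_bead[a], 0] += fx
                f_nuc[a_bead[a], 1] += fy
            if mt_n[m] < 2:
                f_mt[m, 0, 0] -= fx
                f_mt[m, 0, 1] -= fy
            else:
                f_mt[m, j, 0] -= (1.0 - frac) * fx
                f_mt[m, j, 1] -= (1.0 - frac) * fy
                f_mt[m, j + 1, 0] -= frac * fx
                f_mt[m, j + 1, 1] -= frac * fy

        # ---- dynein: attachment ------------------------------------------
        if A > 0:
            for a in range(A):
                best_d2[a] = 1e30
                best_m[a] = -1
                best_b[a] = -1
            rc2 = r_cap * r_cap
            for c in range(cnt[2]):
                m = tm_m[c]
                b = tm_b[c]
                if b >= mt_n[m] or era[m, b] != tm_e[c]:
                    continue
                a = mem_aid[tm_t[c]]
                if a < 0 or a_bound[a]:
                    continue
                dx = mt_pos[m, b, 0] - mem[tm_t[c], 0]
                dy = mt_pos[m, b, 1] - mem[tm_t[c], 1]
                d2 = dx * dx + dy * dy
                if d2 < rc2 and d2 < best_d2[a]:
                    best_d2[a] = d2
                    best_m[a] = m
                    best_b[a] = b
            for c in range(cnt[3]):
                m = tn_m[c]
                b = tn_b[c]
                if b >= mt_n[m] or era[m, b] != tn_e[c]:
                    continue
                a = nuc_aid[tn_t[c]]
                if a < 0 or a_bound[a]:
                    continue
                dx = mt_pos[m, b, 0] - nuc[tn_t[c], 0]
                dy = mt_pos[m, b, 1] - nuc[tn_t[c], 1]
                d2 = dx * dx + dy * dy
                if d2 < rc2 and d2 < best_d2[a]:
                    best_d2[a] = d2
                    best_m[a] = m
                    best_b[a] = b
            for a in range(A):
                if (not a_bound[a]) and best_m[a] >= 0 and \
                        u_att[s, a] < PF[PF_P_ON]:
                    a_bound[a] = True
                    a_mt[a] = best_m[a]
                    a_arc[a] = best_b[a] * sigma

        # ---- crosstalk: contraction force + protrusion velocity ----------
        outward_normals_kernel(mem, normals)
        fc0 = PF[PF_F_CONTR0]
        vp0 = PF[PF_V_PROT0]
        for i in range(nm):
            f_mem[i, 0] -= fc0 * ss[i] * normals[i, 0]
            f_mem[i, 1] -= fc0 * ss[i] * normals[i, 1]
            vact[i, 0] += vp0 * sg[i] * normals[i, 0]
            vact[i, 1] += vp0 * sg[i] * normals[i, 1]

        # ---- chemotactic bias --------------------------------------------
        vch = PF[PF_V_CHEMO]
        if vch > 0.0:
            for i in range(nm):
                vact[i, 0] += vch * PF[PF_CHEMO_X]
                vact[i, 1] += vch * PF[PF_CHEMO_Y]

        # ---- sub-cycled forward Euler update -----------------------------
        # the stiff local elasticity (stretch + bend) is re-evaluated on a
        # finer substep; the slow forces and active velocities are held
        # constant across the step.  Displacements are guarded per substep
        # at the per-step bound scaled by 1/n_sub.
        n_sub = int(PF[PF_N_SUB])
        dts = dt / n_sub
        step_disp = 0.0  # cumulative per-step bound: sum of substep maxima
        inv_gm = dts / PF[PF_GAMMA_MEM]
        inv_gn = dts / PF[PF_GAMMA_NUC]
        inv_gt = dts / PF[PF_GAMMA_MT]
        for sub in range(n_sub):
            maxstep2 = 0.0
            for i in range(nm):
                e_mem[i, 0] = 0.0
                e_mem[i, 1] = 0.0
            for j in range(nn):
                e_nuc[j, 0] = 0.0
                e_nuc[j, 1] = 0.0
            for m in range(N):
                for b in range(mt_n[m]):
                    e_mt[m, b, 0] = 0.0
                    e_mt[m, b, 1] = 0.0
            stretch_ring_kernel(mem, PF[PF_KS_MEM], PF[PF_L0_MEM], e_mem)
            bend_ring_kernel(mem, PF[PF_KAPPA_MEM], PF[PF_L0_MEM],
                             PF[PF_THETA0_MEM], e_mem)
            stretch_ring_kernel(nuc, PF[PF_KS_NUC], PF[PF_L0_NUC], e_nuc)
            bend_ring_kernel(nuc, PF[PF_KAPPA_NUC], PF[PF_L0_NUC],
                             PF[PF_THETA0_NUC], e_nuc)
            for m in range(N):
                nb = mt_n[m]
                if nb >= 2:
                    stretch_chain_kernel(mt_pos[m], nb, PF[PF_KS_MT], sigma,
                                         e_mt[m])
                    if nb >= 3:
                        bend_chain_kernel(mt_pos[m], nb, PF[PF_KAPPA_MT],
                                          sigma, e_mt[m])
            for i in range(nm):
                dx = inv_gm * (f_mem[i, 0] + e_mem[i, 0]) + dts * vact[i, 0]
                dy = inv_gm * (f_mem[i, 1] + e_mem[i, 1]) + dts * vact[i, 1]
                if not (math.isfinite(dx) and math.isfinite(dy)):
                    return ERR_NONFINITE, s
                d2 = dx * dx + dy * dy
                if d2 > maxstep2:
                    maxstep2 = d2
                    cnt[5] = 0
                    cnt[6] = i
                    cnt[7] = 0
                mem[i, 0] += dx
                mem[i, 1] += dy
            for j in range(nn):
                dx = inv_gn * (f_nuc[j, 0] + e_nuc[j, 0])
                dy = inv_gn * (f_nuc[j, 1] + e_nuc[j, 1])
                if not (math.isfinite(dx) and math.isfinite(dy)):
                    return ERR_NONFINITE, s
                d2 = dx * dx + dy * dy
                if d2 > maxstep2:
                    maxstep2 = d2
                    cnt[5] = 1
                    cnt[6] = j
                    cnt[7] = 0
                nuc[j, 0] += dx
                nuc[j, 1] += dy
            fcx = f_cen[0]
            fcy = f_cen[1]
            for m in range(N):
                # minus-end force is delivered to the centrosome
                fcx += f_mt[m, 0, 0] + e_mt[m, 0, 0]
                fcy += f_mt[m, 0, 1] + e_mt[m, 0, 1]
                for b in range(1, mt_n[m]):
                    dx = inv_gt * (f_mt[m, b, 0] + e_mt[m, b, 0])
                    dy = inv_gt * (f_mt[m, b, 1] + e_mt[m, b, 1])
                    if not (math.isfinite(dx) and math.isfinite(dy)):
                        return ERR_NONFINITE, s
                    d2 = dx * dx + dy * dy
                    if d2 > maxstep2:
                        maxstep2 = d2
                        cnt[5] = 2
                        cnt[6] = m
                        cnt[7] = b
                    mt_pos[m, b, 0] += dx
                    mt_pos[m, b, 1] += dy
            dx = dts * fcx / PF[PF_GAMMA_CEN]
            dy = dts * fcy / PF[PF_GAMMA_CEN]
            if not (math.isfinite(dx) and math.isfinite(dy)):
                return ERR_NONFINITE, s
            d2 = dx * dx + dy * dy
            if d2 > maxstep2:
                maxstep2 = d2
            cen[0] += dx
            cen[1] += dy
            for m in range(N):
                mt_pos[m, 0, 0] = cen[0]
                mt_pos[m, 0, 1] = cen[1]
            step_disp += math.sqrt(maxstep2)
            if step_disp * step_disp > max_disp2:
                cnt[7] = int(step_disp * 1e6)  # accumulated step motion, pm
                return ERR_DISPLACEMENT, s

    return OK, n_steps


# ==========================================================================
# Python-side wrapper for pair lists (used by mechanics.all_steric_forces
# and by the engine)
# ==========================================================================

class PairLists:
    """Preallocated Verlet pair lists plus reference positions."""

    CAP_MM = 1 << 14
    CAP_MN = 1 << 13
    CAP_TM = 1 << 17
    CAP_TN = 1 << 16
    CAP_SB = 1 << 17

    def __init__(self, nm: int, nn: int, N: int, maxB: int, skin: float):
        ii = np.int64
        self.skin = skin
        self.mm_i = np.zeros(self.CAP_MM, ii)
        self.mm_j = np.zeros(self.CAP_MM, ii)
        self.mn_i = np.zeros(self.CAP_MN, ii)
        self.mn_j = np.zeros(self.CAP_MN, ii)
        self.tm_m = np.zeros(self.CAP_TM, ii)
        self.tm_b = np.zeros(self.CAP_TM, ii)
        self.tm_e = np.zeros(self.CAP_TM, ii)
        self.tm_t = np.zeros(self.CAP_TM, ii)
        self.tn_m = np.zeros(self.CAP_TN, ii)
        self.tn_b = np.zeros(self.CAP_TN, ii)
        self.tn_e = np.zeros(self.CAP_TN, ii)
        self.tn_t = np.zeros(self.CAP_TN, ii)
        self.sb_type = np.zeros(self.CAP_SB, ii)
        self.sb_i1 = np.zeros(self.CAP_SB, ii)
        self.sb_i2 = np.zeros(self.CAP_SB, ii)
        self.sb_e = np.zeros(self.CAP_SB, ii)
        self.sb_kind = np.zeros(self.CAP_SB, ii)
        self.sb_k = np.zeros(self.CAP_SB, ii)
        self.cnt = np.zeros(8, ii)
        self.ref_mem = np.zeros((nm, 2))
        self.ref_nuc = np.zeros((nn, 2))
        self.ref_mt = np.zeros((N, maxB, 2))

    @classmethod
    def build(cls, state, env, params, skin: float | None = None) -> "PairLists":
        if skin is None:
            skin = params.skin
        mts = state.mts
        pl = cls(state.membrane.n, state.nucleus.n, mts.N, mts.max_beads, skin)
        sigma = params.sigma_mt
        r_bb = RC * sigma + skin
        r_tm = max(RC * sigma, params.dynein.r_capture) + skin
        r_sb = (RC - 1.0) * sigma + skin
        st = build_pairs_kernel(
            state.membrane.pos, state.nucleus.pos, mts.pos, mts.n_beads,
            mts.era, env.obstacle_array(), env.wall_array(),
            r_bb, r_tm, r_sb,
            pl.mm_i, pl.mm_j, pl.mn_i, pl.mn_j,
            pl.tm_m, pl.tm_b, pl.tm_e, pl.tm_t,
            pl.tn_m, pl.tn_b, pl.tn_e, pl.tn_t,
            pl.sb_type, pl.sb_i1, pl.sb_i2, pl.sb_e, pl.sb_kind, pl.sb_k,
            pl.cnt)
        if st != 0:
            raise RuntimeError("pair-list capacity exceeded")
        pl.ref_mem[:] = state.membrane.pos
        pl.ref_nuc[:] = state.nucleus.pos
        pl.ref_mt[:] = mts.pos
        return pl


def eval_steric(state, env, params, pl: PairLists,
                f_mem, f_nuc, f_mt, f_cen) -> None:
    """Evaluate all steric forces from prebuilt pair lists (wrapper)."""
    mts = state.mts
    f_cen_buf = np.zeros((1, 2))
    eval_steric_kernel(
        state.membrane.pos, state.nucleus.pos, state.centrosome,
        mts.pos, mts.n_beads, mts.era,
        env.obstacle_array(), env.wall_array(),
        params.sigma_mt, params.eps_wca, params.f_cap, params.f_cap_wall,
        pl.mm_i, pl.mm_j, pl.mn_i, pl.mn_j,
        pl.tm_m, pl.tm_b, pl.tm_e, pl.tm_t,
        pl.tn_m, pl.tn_b, pl.tn_e, pl.tn_t,
        pl.sb_type, pl.sb_i1, pl.sb_i2, pl.sb_e, pl.sb_kind, pl.sb_k,
        pl.cnt, f_mem, f_nuc, f_mt, f_cen_buf[0])
    f_cen += f_cen_buf[0]
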