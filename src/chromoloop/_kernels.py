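"""Numba-compiled inner loops: forces, Langevin integration, contact finding.

Everything here operates on plain arrays in reduced units and is exercised
against the vectorised numpy reference in :mod:`chromoloop.model` by the test
suite.  Single-threaded by design so that a run is bit-reproducible for a
given seed.

Neighbor search uses a cell grid with lazy (stamp-based) resets and a Verlet
skin: the pair list is valid until some particle has moved more than half the
skin, so the O(N) grid pass runs only every several steps.
"""

from __future__ import annotations

import numpy as np
from numba import njit

LJ_CUTOFF = 2.0 ** (1.0 / 6.0)
R_FLOOR = 0.3

#: Verlet skin added to the repulsion range for the candidate-pair list
SKIN = 1.5

# status codes returned by integrate_run
OK = 0
BLOWUP = 1
PAIR_OVERFLOW = 2


@njit(cache=True)
def pair_capacity(n: int) -> int:
    return max(4096, 160 * n)


# ---------------------------------------------------------------------------
# neighbor list (cell grid with lazy stamp resets + Verlet skin)
# ---------------------------------------------------------------------------

@njit(cache=True, fastmath=True)
def _build_pairs(x0, x1, x2, rlist, excl_keys, pair_i, pair_j, cid, order, scratch):
    """Fill pair_i/pair_j with candidate nonbonded pairs within rlist.

    Coordinates come as three flat float32 component arrays.  Ring-adjacent
    pairs (separation < 2 along the ring) and pairs whose key i*n+j appears
    in the sorted excl_keys array are skipped.  Particles are counting-sorted
    by cell so each neighbor cell is a contiguous range of ``order``; the
    grid is padded by one empty cell per side so the half-neighborhood scan
    needs no bounds checks.  Returns the number of pairs, -1 on pair
    overflow, -2 when the scratch is too small for the bounding box.
    """
    n = x0.shape[0]
    cap = pair_i.shape[0]
    xmin0 = x0.min()
    xmin1 = x1.min()
    xmin2 = x2.min()
    inv_cell = 1.0 / rlist
    ncx = int((x0.max() - xmin0) * inv_cell) + 3
    ncy = int((x1.max() - xmin1) * inv_cell) + 3
    ncz = int((x2.max() - xmin2) * inv_cell) + 3
    ncells = ncx * ncy * ncz
    if ncells + 1 > scratch.shape[0]:
        return -2
    start = scratch[: ncells + 1]
    for c in range(ncells + 1):
        start[c] = 0
    for i in range(n):
        cx = int((x0[i] - xmin0) * inv_cell) + 1
        cy = int((x1[i] - xmin1) * inv_cell) + 1
        cz = int((x2[i] - xmin2) * inv_cell) + 1
        c = (cx * ncy + cy) * ncz + cz
        cid[i] = c
        start[c + 1] += 1
    for c in range(ncells):
        start[c + 1] += start[c]
    for i in range(n):
        c = cid[i]
        order[start[c]] = i
        start[c] += 1
    # start[c] now holds the END of cell c's range; start[c-1] its beginning
    rlist2 = np.float32(rlist * rlist)
    cnt = 0
    # 13 half-neighborhood offsets (lexicographically positive)
    offs = np.empty(13, dtype=np.int64)
    m = 0
    for dx in range(-1, 2):
        for dy in range(-1, 2):
            for dz in range(-1, 2):
                if dx > 0 or (dx == 0 and dy > 0) or (dx == 0 and dy == 0 and dz > 0):
                    offs[m] = (dx * ncy + dy) * ncz + dz
                    m += 1
    for a in range(n):
        i = order[a]
        ci = cid[i]
        xi0 = x0[i]
        xi1 = x1[i]
        xi2 = x2[i]
        # same cell: b > a within the cell range avoids double counting
        hi = start[ci]
        for b in range(a + 1, hi):
            j = order[b]
            ds = j - i if j > i else i - j
            sep = ds if ds < n - ds else n - ds
            if sep >= 2:
                ddx = xi0 - x0[j]
                ddy = xi1 - x1[j]
                ddz = xi2 - x2[j]
                r2 = ddx * ddx + ddy * ddy + ddz * ddz
                if r2 < rlist2:
                    if cnt >= cap:
                        return -1
                    pair_i[cnt] = i
                    pair_j[cnt] = j
                    cnt += 1
        # 13 forward neighbor cells: full contiguous ranges
        for o in range(13):
            c2 = ci + offs[o]
            lo = start[c2 - 1]
            hi = start[c2]
            for b in range(lo, hi):
                j = order[b]
                ds = j - i if j > i else i - j
                sep = ds if ds < n - ds else n - ds
                if sep >= 2:
                    ddx = xi0 - x0[j]
                    ddy = xi1 - x1[j]
                    ddz = xi2 - x2[j]
                    r2 = ddx * ddx + ddy * ddy + ddz * ddz
                    if r2 < rlist2:
                        if cnt >= cap:
                            return -1
                        pair_i[cnt] = i
                        pair_j[cnt] = j
                        cnt += 1
    nexcl = excl_keys.shape[0]
    if nexcl > 0:
        kept = 0
        for p in range(cnt):
            a = pair_i[p]
            b = pair_j[p]
            if a > b:
                a, b = b, a
            key = a * n + b
            lo = 0
            hi = nexcl
            while lo < hi:
                mid = (lo + hi) // 2
                if excl_keys[mid] < key:
                    lo = mid + 1
                else:
                    hi = mid
            if lo < nexcl and excl_keys[lo] == key:
                continue
            pair_i[kept] = pair_i[p]
            pair_j[kept] = pair_j[p]
            kept += 1
        cnt = kept
    return cnt


# ---------------------------------------------------------------------------
# forces
# ---------------------------------------------------------------------------

@njit(cache=True, fastmath=True)
def _compute_forces(
    x0, x1, x2,
    f0, f1, f2,
    b0, b1, b2, blen,
    gu0, gu1, gu2,
    gv0, gv1, gv2,
    pair_i, pair_j, npairs,
    loop_a, loop_b,
    bond_k, kang, ecut, crossing, phantom,
    conf_r, conf_slope, force_cap,
):
    """Forces for the current conformation (SoA float32 layout).

    Terms: ring harmonic bonds, loop bonds, three-point bending, soft-core
    excluded volume over the candidate pair list, and linear spherical
    confinement.  All passes over the chain are unit-stride so the compiler
    can vectorise them.
    """
    n = x0.shape[0]
    one = np.float32(1.0)
    kb2 = np.float32(2.0 * bond_k)
    ka = np.float32(kang)

    # bond vectors b_i = x_{i+1} - x_i and lengths
    for i in range(n - 1):
        b0[i] = x0[i + 1] - x0[i]
        b1[i] = x1[i + 1] - x1[i]
        b2[i] = x2[i + 1] - x2[i]
    b0[n - 1] = x0[0] - x0[n - 1]
    b1[n - 1] = x1[0] - x1[n - 1]
    b2[n - 1] = x2[0] - x2[n - 1]
    for i in range(n):
        blen[i] = np.sqrt(b0[i] * b0[i] + b1[i] * b1[i] + b2[i] * b2[i])

    # ring bonds: per-bond tension vectors (in gu scratch), then
    # f_i = gb_i - gb_{i-1}
    for i in range(n):
        co = kb2 * (blen[i] - one) / blen[i]
        gu0[i] = co * b0[i]
        gu1[i] = co * b1[i]
        gu2[i] = co * b2[i]
    for i in range(1, n):
        f0[i] = gu0[i] - gu0[i - 1]
        f1[i] = gu1[i] - gu1[i - 1]
        f2[i] = gu2[i] - gu2[i - 1]
    f0[0] = gu0[0] - gu0[n - 1]
    f1[0] = gu1[0] - gu1[n - 1]
    f2[0] = gu2[0] - gu2[n - 1]

    # bending: angle at monomer i between bonds u = b_{i-1} and v = b_i;
    # dU/du = -k dc/du with dc/du = v/(|u||v|) - c u/|u|^2
    if kang != 0.0:
        for i in range(n):
            ip = i - 1 if i > 0 else n - 1
            lu = blen[ip]
            lv = blen[i]
            inv = one / (lu * lv)
            c = (b0[ip] * b0[i] + b1[ip] * b1[i] + b2[ip] * b2[i]) * inv
            c = min(max(c, -one), one)
            ilu2 = inv * inv * lv * lv
            ilv2 = inv * inv * lu * lu
            gu0[i] = -ka * (b0[i] * inv - c * b0[ip] * ilu2)
            gu1[i] = -ka * (b1[i] * inv - c * b1[ip] * ilu2)
            gu2[i] = -ka * (b2[i] * inv - c * b2[ip] * ilu2)
            gv0[i] = -ka * (b0[ip] * inv - c * b0[i] * ilv2)
            gv1[i] = -ka * (b1[ip] * inv - c * b1[i] * ilv2)
            gv2[i] = -ka * (b2[ip] * inv - c * b2[i] * ilv2)
        # scatter: f[i-1] += gu_i ; f[i] -= gu_i - gv_i ; f[i+1] -= gv_i
        for i in range(1, n):
            f0[i - 1] += gu0[i]
            f1[i - 1] += gu1[i]
            f2[i - 1] += gu2[i]
        f0[n - 1] += gu0[0]
        f1[n - 1] += gu1[0]
        f2[n - 1] += gu2[0]
        for i in range(n):
            f0[i] -= gu0[i] - gv0[i]
            f1[i] -= gu1[i] - gv1[i]
            f2[i] -= gu2[i] - gv2[i]
        for i in range(n - 1):
            f0[i + 1] -= gv0[i]
            f1[i + 1] -= gv1[i]
            f2[i + 1] -= gv2[i]
        f0[0] -= gv0[n - 1]
        f1[0] -= gv1[n - 1]
        f2[0] -= gv2[n - 1]

    # loop bonds
    for l in range(loop_a.shape[0]):
        i = loop_a[l]
        j = loop_b[l]
        dx = x0[i] - x0[j]
        dy = x1[i] - x1[j]
        dz = x2[i] - x2[j]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        if r > 0.0:
            g = -kb2 * (r - one) / r
            f0[i] += g * dx
            f1[i] += g * dy
            f2[i] += g * dz
            f0[j] -= g * dx
            f1[j] -= g * dy
            f2[j] -= g * dz

    # excluded volume
    if not phantom:
        half = np.float32(0.5 * ecut)
        inv_ecut2 = np.float32(2.0 / ecut)
        cut2 = np.float32(LJ_CUTOFF * LJ_CUTOFF)
        fl10 = np.float32(R_FLOOR**10)
        for p in range(npairs):
            i = pair_i[p]
            j = pair_j[p]
            dx = x0[i] - x0[j]
            dy = x1[i] - x1[j]
            dz = x2[i] - x2[j]
            r2 = dx * dx + dy * dy + dz * dz
            if r2 >= cut2:
                # rt >= r, so the pair is beyond the repulsion range
                continue
            rt2 = (r2 * r2 * r2 * r2 * r2 + fl10) ** np.float32(0.2)
            if rt2 >= cut2:
                continue
            inv2 = one / rt2
            inv6 = inv2 * inv2 * inv2
            u_raw = np.float32(4.0) * (inv6 * inv6 - inv6) + one
            rt = np.sqrt(rt2)
            du_drt = (np.float32(-48.0) * inv6 * inv6 + np.float32(24.0) * inv6) / rt
            if crossing and u_raw > half:
                arg = u_raw * inv_ecut2 - one
                if arg > np.float32(60.0):
                    arg = np.float32(60.0)
                ch = np.cosh(arg)
                du_drt = du_drt / (ch * ch)
            r = np.sqrt(r2)
            if r > 0.0:
                # (r/rt)^9 = t^4 sqrt(t) with t = r2/rt2
                t = r2 * inv2
                t2 = t * t
                drt_dr = t2 * t2 * np.sqrt(t)
                g = -du_drt * drt_dr / r
                f0[i] += g * dx
                f1[i] += g * dy
                f2[i] += g * dz
                f0[j] -= g * dx
                f1[j] -= g * dy
                f2[j] -= g * dz

    # confinement
    if conf_r > 0.0:
        cr2 = np.float32(conf_r * conf_r)
        slope = np.float32(conf_slope)
        for i in range(n):
            rad2 = x0[i] * x0[i] + x1[i] * x1[i] + x2[i] * x2[i]
            if rad2 > cr2:
                g = -slope / np.sqrt(rad2)
                f0[i] += g * x0[i]
                f1[i] += g * x1[i]
                f2[i] += g * x2[i]

    if force_cap > 0.0:
        fc = np.float32(force_cap)
        for i in range(n):
            f0[i] = min(max(f0[i], -fc), fc)
            f1[i] = min(max(f1[i], -fc), fc)
            f2[i] = min(max(f2[i], -fc), fc)


# ---------------------------------------------------------------------------
# Langevin integration (velocity Verlet + Andersen thermostat, optional
# batched Ornstein-Uhlenbeck friction)
# ---------------------------------------------------------------------------

@njit(cache=True, fastmath=True)
def integrate_run(
    x,
    v,
    n_blocks,
    steps_per_block,
    dt,
    gamma,
    coll_prob,
    loop_a,
    loop_b,
    bond_k,
    kang,
    ecut,
    crossing,
    phantom,
    conf_r,
    conf_slope,
    force_cap,
    excl_keys,
    seed,
    record_from,
    rec_coords,
    ke_out,
    maxbond_out,
    disp_out,
):
    """Integrate ``n_blocks`` blocks of ``steps_per_block`` Langevin steps.

    ``x`` and ``v`` are (N, 3) float64 arrays, updated in place at the end of
    the run; internally the state is kept in float32 component arrays for
    SIMD throughput.  Records coordinates (float32) for every block index >=
    record_from into rec_coords and per-block diagnostics (block-averaged
    kinetic energy per monomer, max bond length, mean displacement from the
    start) for all blocks.  Returns (status, offending_block).
    """
    np.random.seed(seed)
    n = x.shape[0]
    x0 = np.empty(n, dtype=np.float32)
    x1 = np.empty(n, dtype=np.float32)
    x2 = np.empty(n, dtype=np.float32)
    v0 = np.empty(n, dtype=np.float32)
    v1 = np.empty(n, dtype=np.float32)
    v2 = np.empty(n, dtype=np.float32)
    for i in range(n):
        x0[i] = x[i, 0]
        x1[i] = x[i, 1]
        x2[i] = x[i, 2]
        v0[i] = v[i, 0]
        v1[i] = v[i, 1]
        v2[i] = v[i, 2]
    xs0 = x0.copy()
    xs1 = x1.copy()
    xs2 = x2.copy()
    rlist = LJ_CUTOFF + SKIN
    cap = pair_capacity(n)
    pair_i = np.empty(cap, dtype=np.int64)
    pair_j = np.empty(cap, dtype=np.int64)
    # grid scratch: sized for a bounding box of ~80 cells per side
    grid_scratch = np.empty(80 * 80 * 80, dtype=np.int64)
    cid = np.empty(n, dtype=np.int64)
    order = np.empty(n, dtype=np.int64)
    npairs = 0
    if not phantom:
        npairs = _build_pairs(
            x0, x1, x2, rlist, excl_keys, pair_i, pair_j, cid, order, grid_scratch
        )
        if npairs < 0:
            return PAIR_OVERFLOW, 0
    xr0 = x0.copy()
    xr1 = x1.copy()
    xr2 = x2.copy()
    f0 = np.zeros(n, dtype=np.float32)
    f1 = np.zeros(n, dtype=np.float32)
    f2 = np.zeros(n, dtype=np.float32)
    b0 = np.empty(n, dtype=np.float32)
    b1 = np.empty(n, dtype=np.float32)
    b2 = np.empty(n, dtype=np.float32)
    blen = np.empty(n, dtype=np.float32)
    gu0 = np.empty(n, dtype=np.float32)
    gu1 = np.empty(n, dtype=np.float32)
    gu2 = np.empty(n, dtype=np.float32)
    gv0 = np.empty(n, dtype=np.float32)
    gv1 = np.empty(n, dtype=np.float32)
    gv2 = np.empty(n, dtype=np.float32)
    _compute_forces(
        x0, x1, x2, f0, f1, f2, b0, b1, b2, blen,
        gu0, gu1, gu2, gv0, gv1, gv2,
        pair_i, pair_j, npairs, loop_a, loop_b,
        bond_k, kang, ecut, crossing, phantom, conf_r, conf_slope, force_cap,
    )
    # the OU (friction) step is applied every o_interval steps with the
    # correspondingly compounded decay; the OU map preserves the canonical
    # distribution exactly at any interval, and batching keeps the per-step
    # cost dominated by the force evaluation
    o_interval = 10
    c1 = np.float32(np.exp(-gamma * dt * o_interval))
    c2 = np.float32(np.sqrt(1.0 - np.exp(-2.0 * gamma * dt * o_interval)))
    inv_log_q = 1.0 / np.log(1.0 - coll_prob) if coll_prob > 0.0 else 0.0
    half_dt = np.float32(0.5 * dt)
    skin_f = np.float32(SKIN)
    rec = 0
    step_count = 0
    for block in range(n_blocks):
        ke_acc = 0.0
        for _ in range(steps_per_block):
            # B + A (first half)
            for i in range(n):
                v0[i] += half_dt * f0[i]
                x0[i] += half_dt * v0[i]
            for i in range(n):
                v1[i] += half_dt * f1[i]
                x1[i] += half_dt * v1[i]
            for i in range(n):
                v2[i] += half_dt * f2[i]
                x2[i] += half_dt * v2[i]
            # O (Ornstein-Uhlenbeck), batched
            if gamma > 0.0 and step_count % o_interval == 0:
                noise = np.random.standard_normal(3 * n)
                for i in range(n):
                    v0[i] = c1 * v0[i] + c2 * np.float32(noise[i])
                    v1[i] = c1 * v1[i] + c2 * np.float32(noise[n + i])
                    v2[i] = c1 * v2[i] + c2 * np.float32(noise[2 * n + i])
            # Andersen collisions: Bernoulli(coll_prob) per particle via
            # geometric skipping (costs ~n*coll_prob RNG draws per step)
            if coll_prob > 0.0:
                i = int(np.log(np.random.random()) * inv_log_q)
                while i < n:
                    v0[i] = np.float32(np.random.normal())
                    v1[i] = np.float32(np.random.normal())
                    v2[i] = np.float32(np.random.normal())
                    i += 1 + int(np.log(np.random.random()) * inv_log_q)
            step_count += 1
            # A (second half)
            for i in range(n):
                x0[i] += half_dt * v0[i]
                x1[i] += half_dt * v1[i]
                x2[i] += half_dt * v2[i]
            # neighbor-list validity: an unseen pair can close the skin gap
            # only if the two largest displacements since the last build sum
            # to more than the skin
            if not phantom:
                max1 = np.float32(0.0)
                max2 = np.float32(0.0)
                for i in range(n):
                    ddx = x0[i] - xr0[i]
                    ddy = x1[i] - xr1[i]
                    ddz = x2[i] - xr2[i]
                    d2 = ddx * ddx + ddy * ddy + ddz * ddz
                    if d2 > max1:
                        max2 = max1
                        max1 = d2
                    elif d2 > max2:
                        max2 = d2
                if np.sqrt(max1) + np.sqrt(max2) > skin_f:
                    npairs = _build_pairs(
                        x0, x1, x2, rlist, excl_keys, pair_i, pair_j,
                        cid, order, grid_scratch,
                    )
                    if npairs < 0:
                        for i in range(n):
                            x[i, 0] = x0[i]
                            x[i, 1] = x1[i]
                            x[i, 2] = x2[i]
                            v[i, 0] = v0[i]
                            v[i, 1] = v1[i]
                            v[i, 2] = v2[i]
                        return PAIR_OVERFLOW, block
                    for i in range(n):
                        xr0[i] = x0[i]
                        xr1[i] = x1[i]
                        xr2[i] = x2[i]
            _compute_forces(
                x0, x1, x2, f0, f1, f2, b0, b1, b2, blen,
                gu0, gu1, gu2, gv0, gv1, gv2,
                pair_i, pair_j, npairs, loop_a, loop_b,
                bond_k, kang, ecut, crossing, phantom, conf_r, conf_slope,
                force_cap,
            )
            # B + kinetic energy
            ke = np.float32(0.0)
            for i in range(n):
                v0[i] += half_dt * f0[i]
                v1[i] += half_dt * f1[i]
                v2[i] += half_dt * f2[i]
                ke += v0[i] * v0[i] + v1[i] * v1[i] + v2[i] * v2[i]
            ke_acc += 0.5 * float(ke) / n
        # block diagnostics
        ok = True
        maxbond = 0.0
        disp = 0.0
        for i in range(n):
            if not (np.isfinite(x0[i]) and np.isfinite(x1[i]) and np.isfinite(x2[i])):
                ok = False
                break
            j = i + 1 if i < n - 1 else 0
            ddx = x0[i] - x0[j]
            ddy = x1[i] - x1[j]
            ddz = x2[i] - x2[j]
            b = np.sqrt(ddx * ddx + ddy * ddy + ddz * ddz)
            if b > maxbond:
                maxbond = b
            ddx = x0[i] - xs0[i]
            ddy = x1[i] - xs1[i]
            ddz = x2[i] - xs2[i]
            disp += np.sqrt(ddx * ddx + ddy * ddy + ddz * ddz)
        if not ok:
            for i in range(n):
                x[i, 0] = x0[i]
                x[i, 1] = x1[i]
                x[i, 2] = x2[i]
            return BLOWUP, block
        ke_out[block] = ke_acc / steps_per_block
        maxbond_out[block] = maxbond
        disp_out[block] = disp / n
        if block >= record_from:
            for i in range(n):
                rec_coords[rec, i, 0] = x0[i]
                rec_coords[rec, i, 1] = x1[i]
                rec_coords[rec, i, 2] = x2[i]
            rec += 1
    # write the final state back to the float64 interface arrays
    for i in range(n):
        x[i, 0] = x0[i]
        x[i, 1] = x1[i]
        x[i, 2] = x2[i]
        v[i, 0] = v0[i]
        v[i, 1] = v1[i]
        v[i, 2] = v2[i]
    return OK, n_blocks


# ---------------------------------------------------------------------------
# contact finding
# ---------------------------------------------------------------------------

@njit(cache=True)
def contact_pairs_kernel(x, cutoff, min_sep, pair_i, pair_j):
    """All unordered pairs at Euclidean distance strictly < cutoff with ring
    separation >= min_sep.  Returns count or -1 on overflow."""
    n = x.shape[0]
    head = np.empty(128 * 128 * 128, dtype=np.int64)
    stamp = np.zeros(128 * 128 * 128, dtype=np.int64)
    nxt = np.empty(n, dtype=np.int64)
    return _contacts_one(x, cutoff, min_sep, pair_i, pair_j, head, stamp, 1, nxt)


@njit(cache=True, fastmath=True)
def _contacts_one(x, cutoff, min_sep, pair_i, pair_j, head, stamp, cur, nxt):
    n = x.shape[0]
    cap = pair_i.shape[0]
    xmin0 = x[:, 0].min()
    xmin1 = x[:, 1].min()
    xmin2 = x[:, 2].min()
    inv_cell = 1.0 / cutoff
    ncx = int((x[:, 0].max() - xmin0) * inv_cell) + 1
    ncy = int((x[:, 1].max() - xmin1) * inv_cell) + 1
    ncz = int((x[:, 2].max() - xmin2) * inv_cell) + 1
    if ncx * ncy * ncz > head.shape[0]:
        return -2
    cix = np.empty(n, dtype=np.int64)
    for i in range(n):
        cx = int((x[i, 0] - xmin0) * inv_cell)
        cy = int((x[i, 1] - xmin1) * inv_cell)
        cz = int((x[i, 2] - xmin2) * inv_cell)
        c = (cx * ncy + cy) * ncz + cz
        cix[i] = c
        if stamp[c] != cur:
            stamp[c] = cur
            head[c] = -1
        nxt[i] = head[c]
        head[c] = i
    cut2 = cutoff * cutoff
    cnt = 0
    nyz = ncy * ncz
    for i in range(n):
        ci = cix[i]
        cz0 = ci % ncz
        cy0 = (ci // ncz) % ncy
        cx0 = ci // nyz
        for dx in range(-1, 2):
            cx = cx0 + dx
            if cx < 0 or cx >= ncx:
                continue
            for dy in range(-1, 2):
                cy = cy0 + dy
                if cy < 0 or cy >= ncy:
                    continue
                base = (cx * ncy + cy) * ncz
                for dz in range(-1, 2):
                    cz = cz0 + dz
                    if cz < 0 or cz >= ncz:
                        continue
                    c = base + cz
                    if stamp[c] != cur:
                        continue
                    j = head[c]
                    while j != -1:
                        if j > i:
                            ds = j - i
                            sep = ds if ds < n - ds else n - ds
                            if sep >= min_sep:
                                ddx = x[i, 0] - x[j, 0]
                                ddy = x[i, 1] - x[j, 1]
                                ddz = x[i, 2] - x[j, 2]
                                if ddx * ddx + ddy * ddy + ddz * ddz < cut2:
                                    if cnt >= cap:
                                        return -1
                                    pair_i[cnt] = i
                                    pair_j[cnt] = j
                                    cnt += 1
                        j = nxt[j]
    return cnt


@njit(cache=True)
def accumulate_contact_map(blocks, cutoff, min_sep, counts):
    """Accumulate contacts of every conformation in ``blocks`` (M, N, 3)
    into the symmetric counts matrix (int64, N x N)."""
    m = blocks.shape[0]
    n = blocks.shape[1]
    cap = 64 * n
    pair_i = np.empty(cap, dtype=np.int64)
    pair_j = np.empty(cap, dtype=np.int64)
    head = np.empty(128 * 128 * 128, dtype=np.int64)
    stamp = np.zeros(128 * 128 * 128, dtype=np.int64)
    nxt = np.empty(n, dtype=np.int64)
    x = np.empty((n, 3))
    cur = 0
    for b in range(m):
        for i in range(n):
            x[i, 0] = blocks[b, i, 0]
            x[i, 1] = blocks[b, i, 1]
            x[i, 2] = blocks[b, i, 2]
        cur += 1
        cnt = _contacts_one(x, cutoff, min_sep, pair_i, pair_j,
                            head, stamp, cur, nxt)
        while cnt == -1:
            cap *= 2
            pair_i = np.empty(cap, dtype=np.int64)
            pair_j = np.empty(cap, dtype=np.int64)
            cur += 1
            cnt = _contacts_one(x, cutoff, min_sep, pair_i, pair_j,
                                head, stamp, cur, nxt)
        if cnt < 0:
            raise ValueError("conformation extent exceeds the contact grid")
        for p in range(cnt):
            counts[pair_i[p], pair_j[p]] += 1
            counts[pair_j[p], pair_i[p]] += 1
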