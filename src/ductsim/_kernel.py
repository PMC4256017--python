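"""Numba kernels for the Metropolis pixel-copy dynamics.

The lattice is a 2D int32 array of agent indices (0 = culture medium) with an
immutable one-pixel medium frame.  Contact energies are summed over 2nd-order
(8-neighbor) pixel pairs; the surface of an agent is its count of 1st-order
(4-neighbor) faces adjoining a different index.  Center-of-mass springs are
evaluated from running coordinate sums so the change in spring length caused
by a single pixel copy is exact.

All energy changes are computed incrementally; ``run_one_mcs`` performs one
copy attempt per lattice pixel and mutates the state arrays in place.
"""

import numpy as np
from numba import njit

# 8-neighborhood offsets (source pixels are drawn uniformly from these)
_DX8 = np.array([1, 1, 0, -1, -1, -1, 0, 1], dtype=np.int64)
_DY8 = np.array([0, 1, 1, 1, 0, -1, -1, -1], dtype=np.int64)


def neighbor_offsets(order: int):
    """(dx, dy) offset tables for the contact-energy neighborhood of a
    given order: 1 -> 4 neighbors, 2 -> 8, 3 -> 12, 4 -> 20."""
    shells = {1: [(1, 0), (-1, 0), (0, 1), (0, -1)],
              2: [(1, 1), (1, -1), (-1, 1), (-1, -1)],
              3: [(2, 0), (-2, 0), (0, 2), (0, -2)],
              4: [(2, 1), (2, -1), (-2, 1), (-2, -1),
                  (1, 2), (1, -2), (-1, 2), (-1, -2)]}
    offs = []
    for k in range(1, order + 1):
        offs.extend(shells[k])
    dx = np.array([o[0] for o in offs], dtype=np.int64)
    dy = np.array([o[1] for o in offs], dtype=np.int64)
    return dx, dy

# The inner loop needs ~1e8 random draws per run; a xorshift64* generator
# with explicit state (seeded per run) is an order of magnitude faster than
# the library Mersenne Twister and keeps trajectories reproducible.
_XMUL = np.uint64(2685821657736338717)
_M20 = np.uint64(0xFFFFF)
_SH12 = np.uint64(12)
_SH25 = np.uint64(25)
_SH27 = np.uint64(27)
_SH20 = np.uint64(20)
_SH40 = np.uint64(40)
_SH11 = np.uint64(11)
_INV53 = 1.0 / 9007199254740992.0  # 2**-53


def make_rng_state(seed: int) -> np.ndarray:
    """Initialize xorshift64* state from a seed via a splitmix64 scramble."""
    mask = 2 ** 64 - 1
    z = (int(seed) + 0x9E3779B97F4A7C15) & mask
    z = ((z ^ (z >> 30)) * 0xBF58476D1CE4E5B9) & mask
    z = ((z ^ (z >> 27)) * 0x94D049BB133111EB) & mask
    z = z ^ (z >> 31)
    if z == 0:
        z = 0x9E3779B97F4A7C15
    return np.array([z], dtype=np.uint64)


@njit(cache=True, inline="always")
def _next_u64(rs):
    s = rs[0]
    s ^= s >> _SH12
    s ^= s << _SH25
    s ^= s >> _SH27
    rs[0] = s
    return s * _XMUL


@njit(cache=True, inline="always")
def _next_unit(rs):
    """Uniform float in [0, 1)."""
    return float(_next_u64(rs) >> _SH11) * _INV53


@njit(cache=True, inline="always")
def _link_delta(a, b, tx, ty, vol, sumx, sumy, lp, llam, llen):
    """Spring-energy change when pixel (tx, ty) moves from agent a to agent b.

    Affected links are those holding a or b; each is counted once.  If the
    copy annihilates agent a (volume hits 0) its links contribute nothing
    afterwards.
    """
    dh = 0.0
    va = vol[a] if a != 0 else 0
    vb = vol[b] if b != 0 else 0
    van = va - 1
    vbn = vb + 1
    for e in (a, b):
        if e == 0:
            continue
        for s in range(4):
            p = lp[e, s]
            if p < 0:
                continue
            if e == b and p == a:
                continue  # the a-b link was already counted from a's side
            lam = llam[e, s]
            L = llen[e, s]
            # old endpoint positions
            ex, ey = sumx[e] / vol[e], sumy[e] / vol[e]
            px, py = sumx[p] / vol[p], sumy[p] / vol[p]
            l_old = np.sqrt((ex - px) ** 2 + (ey - py) ** 2)
            dh -= lam * (l_old - L) ** 2
            # new endpoint positions
            if (e == a and van == 0) or (p == a and van == 0):
                continue  # agent a retires; link energy vanishes
            if e == a:
                ex, ey = (sumx[a] - tx) / van, (sumy[a] - ty) / van
            elif e == b:
                ex, ey = (sumx[b] + tx) / vbn, (sumy[b] + ty) / vbn
            if p == a:
                px, py = (sumx[a] - tx) / van, (sumy[a] - ty) / van
            elif p == b:
                px, py = (sumx[b] + tx) / vbn, (sumy[b] + ty) / vbn
            l_new = np.sqrt((ex - px) ** 2 + (ey - py) ** 2)
            dh += lam * (l_new - L) ** 2
    return dh


@njit(cache=True, inline="always")
def _delta_h(sites, typ, vol, surf, vt, st, lamv, lams, sumx, sumy,
             lp, llam, llen, J, adx, ady, ty, tx, b):
    """Energy change if sites[ty, tx] were overwritten with index b."""
    a = sites[ty, tx]
    if a == b:
        return 0.0
    H, W = sites.shape
    ta = typ[a]
    tb = typ[b]
    dh = 0.0
    # adhesion: every neighborhood pixel pair involving the target pixel
    for k in range(len(adx)):
        ny = ty + ady[k]
        nx = tx + adx[k]
        if ny < 0 or ny >= H or nx < 0 or nx >= W:
            continue
        n = sites[ny, nx]
        tn = typ[n]
        if n != b:
            dh += J[tb, tn]
        if n != a:
            dh -= J[ta, tn]
    # volume constraint
    if a != 0:
        va = vol[a]
        dh += lamv[a] * ((va - 1 - vt[a]) ** 2 - (va - vt[a]) ** 2)
    if b != 0:
        vb = vol[b]
        dh += lamv[b] * ((vb + 1 - vt[b]) ** 2 - (vb - vt[b]) ** 2)
    # surface constraint: only a and b change surface
    if a != 0 or b != 0:
        m_a = 0
        m_b = 0
        if sites[ty, tx + 1] == a:
            m_a += 1
        elif sites[ty, tx + 1] == b:
            m_b += 1
        if sites[ty, tx - 1] == a:
            m_a += 1
        elif sites[ty, tx - 1] == b:
            m_b += 1
        if sites[ty + 1, tx] == a:
            m_a += 1
        elif sites[ty + 1, tx] == b:
            m_b += 1
        if sites[ty - 1, tx] == a:
            m_a += 1
        elif sites[ty - 1, tx] == b:
            m_b += 1
        if a != 0:
            sa = surf[a]
            dh += lams[a] * ((sa + 2 * m_a - 4 - st[a]) ** 2 - (sa - st[a]) ** 2)
        if b != 0:
            sb = surf[b]
            dh += lams[b] * ((sb + 4 - 2 * m_b - st[b]) ** 2 - (sb - st[b]) ** 2)
    # center-of-mass springs
    if (a != 0 and (lp[a, 0] >= 0 or lp[a, 1] >= 0 or lp[a, 2] >= 0 or lp[a, 3] >= 0)) or \
       (b != 0 and (lp[b, 0] >= 0 or lp[b, 1] >= 0 or lp[b, 2] >= 0 or lp[b, 3] >= 0)):
        dh += _link_delta(a, b, tx, ty, vol, sumx, sumy, lp, llam, llen)
    return dh


@njit(cache=True)
def delta_h_at(sites, typ, vol, surf, vt, st, lamv, lams, sumx, sumy,
               lp, llam, llen, J, adx, ady, ty, tx, b):
    """Python-callable wrapper around the inlined incremental energy change."""
    return _delta_h(sites, typ, vol, surf, vt, st, lamv, lams, sumx, sumy,
                    lp, llam, llen, J, adx, ady, ty, tx, b)


@njit(cache=True, inline="always")
def _apply_copy(sites, vol, surf, sumx, sumy, lp, llam, llen, ty, tx, b):
    """Overwrite sites[ty, tx] with b and update the incremental bookkeeping."""
    a = sites[ty, tx]
    if a == b:
        return
    m_a = 0
    m_b = 0
    if sites[ty, tx + 1] == a:
        m_a += 1
    elif sites[ty, tx + 1] == b:
        m_b += 1
    if sites[ty, tx - 1] == a:
        m_a += 1
    elif sites[ty, tx - 1] == b:
        m_b += 1
    if sites[ty + 1, tx] == a:
        m_a += 1
    elif sites[ty + 1, tx] == b:
        m_b += 1
    if sites[ty - 1, tx] == a:
        m_a += 1
    elif sites[ty - 1, tx] == b:
        m_b += 1
    sites[ty, tx] = b
    if a != 0:
        vol[a] -= 1
        surf[a] += 2 * m_a - 4
        sumx[a] -= tx
        sumy[a] -= ty
        if vol[a] == 0:
            # retired agents drop out of all link sets and never reappear
            surf[a] = 0
            for s in range(4):
                p = lp[a, s]
                if p >= 0:
                    for s2 in range(4):
                        if lp[p, s2] == a:
                            lp[p, s2] = -1
                    lp[a, s] = -1
    if b != 0:
        vol[b] += 1
        surf[b] += 4 - 2 * m_b
        sumx[b] += tx
        sumy[b] += ty


@njit(cache=True)
def apply_copy(sites, vol, surf, sumx, sumy, lp, llam, llen, ty, tx, b):
    _apply_copy(sites, vol, surf, sumx, sumy, lp, llam, llen, ty, tx, b)


@njit(cache=True)
def run_one_mcs(sites, typ, vol, surf, vt, st, lamv, lams, sumx, sumy,
                lp, llam, llen, J, adx, ady, temperature, n_attempts, rng_state):
    """One Monte Carlo step: ``n_attempts`` random pixel-copy attempts.

    Returns the number of accepted attempts (no-op copies of an identical
    index have zero energy change and count as accepted).
    """
    H, W = sites.shape
    wspan = np.uint64(W - 2)
    hspan = np.uint64(H - 2)
    accepted = 0
    for _ in range(n_attempts):
        r = _next_u64(rng_state)
        tx = 1 + int(((r & _M20) * wspan) >> _SH20)
        ty = 1 + int((((r >> _SH20) & _M20) * hspan) >> _SH20)
        k = int((r >> _SH40) & np.uint64(7))
        b = sites[ty + _DY8[k], tx + _DX8[k]]
        a = sites[ty, tx]
        if a == b:
            accepted += 1
            continue
        dh = _delta_h(sites, typ, vol, surf, vt, st, lamv, lams, sumx, sumy,
                      lp, llam, llen, J, adx, ady, ty, tx, b)
        if dh <= 0.0 or _next_unit(rng_state) < np.exp(-dh / temperature):
            _apply_copy(sites, vol, surf, sumx, sumy, lp, llam, llen, ty, tx, b)
            accepted += 1
    return accepted
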