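"""Lattice state, energy evaluation, and Metropolis dynamics.

The single source of truth for tissue state is an integer lattice of agent
indices plus per-agent bookkeeping arrays (type, volume, surface, target
constraints, running center-of-mass sums, spring-link slots).  The effective
energy has four terms::

    H = sum_{<ij> : sigma_i != sigma_j} J(tau_i, tau_j)
      + sum_cells lambda_V (V - V_t)^2
      + sum_cells lambda_S (S - S_t)^2
      + sum_links lambda_ij (l_ij - L_ij)^2

``total_energy`` recomputes H from scratch (the oracle); the Metropolis loop
in :mod:`ductsim._kernel` tracks energy changes incrementally.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from . import _kernel
from .params import LEP, MEDIUM, MEP, NECROTIC, SimulationParams


class BookkeepingError(RuntimeError):
    """Lattice and agent records disagree (e.g. unregistered index on lattice)."""


class CpmState:
    """Lattice plus per-agent records.

    Agent index 0 is reserved for culture medium; its constraint parameters
    are zero so it contributes no volume/surface energy.  Arrays are sized to
    ``capacity`` and grown on demand; the live agents are those with
    ``vol > 0`` (and index 0, which is always "live" as medium).
    """

    def __init__(self, width: int, height: int, capacity: int = 512):
        self.width = int(width)
        self.height = int(height)
        self.sites = np.zeros((self.height, self.width), dtype=np.int32)
        self._alloc(capacity)
        self.n_agents = 1  # index 0 = medium

    def _alloc(self, capacity: int) -> None:
        self.capacity = capacity
        self.typ = np.zeros(capacity, dtype=np.uint8)
        self.vol = np.zeros(capacity, dtype=np.int64)
        self.surf = np.zeros(capacity, dtype=np.int64)
        self.vt = np.zeros(capacity, dtype=np.float64)
        self.st = np.zeros(capacity, dtype=np.float64)
        self.lam_v = np.zeros(capacity, dtype=np.float64)
        self.lam_s = np.zeros(capacity, dtype=np.float64)
        self.sum_x = np.zeros(capacity, dtype=np.float64)
        self.sum_y = np.zeros(capacity, dtype=np.float64)
        self.protected = np.zeros(capacity, dtype=bool)
        # four spring-link slots per agent: slots 0-1 hold same-layer
        # partners, slots 2-3 cross-layer partners (two junctions per pair
        # class, mirroring the focal-point-plasticity junction cap)
        self.link_partner = np.full((capacity, 4), -1, dtype=np.int32)
        self.link_lam = np.zeros((capacity, 4), dtype=np.float64)
        self.link_len = np.zeros((capacity, 4), dtype=np.float64)

    def _grow(self, min_capacity: int) -> None:
        new_cap = max(2 * self.capacity, min_capacity)
        old = self.__dict__.copy()
        self._alloc(new_cap)
        n = old["typ"].shape[0]
        for name in ("typ", "vol", "surf", "vt", "st", "lam_v", "lam_s",
                     "sum_x", "sum_y", "protected"):
            getattr(self, name)[:n] = old[name]
        self.link_partner[:n] = old["link_partner"]
        self.link_lam[:n] = old["link_lam"]
        self.link_len[:n] = old["link_len"]

    # ------------------------------------------------------------------ agents
    def new_agent(self, typ: int, vt: float = 0.0, lam_v: float = 0.0,
                  st: float = 0.0, lam_s: float = 0.0) -> int:
        """Register a fresh agent and return its index (pixels painted separately)."""
        idx = self.n_agents
        if idx >= self.capacity:
            self._grow(idx + 1)
        self.n_agents += 1
        self.typ[idx] = typ
        self.vt[idx] = vt
        self.lam_v[idx] = lam_v
        self.st[idx] = st
        self.lam_s[idx] = lam_s
        return idx

    def new_cell(self, typ: int, params: SimulationParams) -> int:
        vt, lam_v, st, lam_s = params.type_params()[typ]
        return self.new_agent(typ, vt, lam_v, st, lam_s)

    def live_indices(self, types=None) -> np.ndarray:
        idx = np.arange(1, self.n_agents)
        alive = self.vol[idx] > 0
        if types is not None:
            alive &= np.isin(self.typ[idx], list(np.atleast_1d(types)))
        return idx[alive]

    def com(self, idx: int) -> tuple[float, float]:
        """(x, y) center of mass of one agent, in pixels."""
        v = self.vol[idx]
        if v == 0:
            raise ValueError(f"agent {idx} has no pixels")
        return self.sum_x[idx] / v, self.sum_y[idx] / v

    def coms(self, indices: np.ndarray) -> np.ndarray:
        v = self.vol[indices].astype(float)
        return np.column_stack([self.sum_x[indices] / v, self.sum_y[indices] / v])

    # -------------------------------------------------------------- bookkeeping
    def refresh(self) -> None:
        """Recompute volumes, surfaces and center-of-mass sums from the lattice."""
        s = self.sites
        flat = s.ravel()
        if flat.max(initial=0) >= self.n_agents:
            raise BookkeepingError("unregistered agent index on lattice")
        minl = self.capacity
        self.vol[:] = np.bincount(flat, minlength=minl)[:minl]
        Y, X = np.mgrid[0:self.height, 0:self.width]
        self.sum_x[:] = np.bincount(flat, weights=X.ravel(), minlength=minl)[:minl]
        self.sum_y[:] = np.bincount(flat, weights=Y.ravel(), minlength=minl)[:minl]
        self.surf[:] = compute_surfaces(s, minl)
        self.vol[0] = 0
        self.surf[0] = 0
        self.sum_x[0] = 0.0
        self.sum_y[0] = 0.0

    def paint(self, mask: np.ndarray, idx: int) -> None:
        self.sites[mask] = idx

    def remove_agent(self, idx: int) -> None:
        """Convert an agent's pixels to medium and retire it from all link sets."""
        mask = self.sites == idx
        if mask.any():
            # neighbors' surfaces change; refresh the affected agents lazily by
            # recomputing everything (removal happens at event cadence, not in
            # the inner loop)
            self.sites[mask] = MEDIUM
        self.vol[idx] = 0
        self.surf[idx] = 0
        self.sum_x[idx] = 0.0
        self.sum_y[idx] = 0.0
        # a retired agent contributes no constraint energy (unlike a cell
        # annihilated by pixel copies, which keeps paying lambda_V*V_t^2)
        self.vt[idx] = 0.0
        self.st[idx] = 0.0
        self.lam_v[idx] = 0.0
        self.lam_s[idx] = 0.0
        self.clear_links(idx)

    def clear_links(self, idx: int) -> None:
        for s in range(4):
            p = self.link_partner[idx, s]
            if p >= 0:
                slots = self.link_partner[p]
                slots[slots == idx] = -1
            self.link_partner[idx, s] = -1
        self.link_lam[idx] = 0.0
        self.link_len[idx] = 0.0

    def check_occupancy(self) -> bool:
        """Invariant: sum of agent volumes equals the count of nonzero pixels."""
        return int(self.vol[1:self.n_agents].sum()) == int(np.count_nonzero(self.sites))

    def iter_links(self):
        """Yield each spring link once as (a, b, lam, L)."""
        for a in range(1, self.n_agents):
            for s in range(4):
                b = self.link_partner[a, s]
                if b > a:
                    yield a, int(b), self.link_lam[a, s], self.link_len[a, s]

    def copy(self) -> "CpmState":
        other = CpmState.__new__(CpmState)
        other.width, other.height = self.width, self.height
        other.capacity = self.capacity
        other.n_agents = self.n_agents
        other.sites = self.sites.copy()
        for name in ("typ", "vol", "surf", "vt", "st", "lam_v", "lam_s",
                     "sum_x", "sum_y", "protected", "link_partner",
                     "link_lam", "link_len"):
            setattr(other, name, getattr(self, name).copy())
        return other


def compute_surfaces(sites: np.ndarray, minlength: int) -> np.ndarray:
    """Per-agent count of 4-neighbor faces adjoining a different index."""
    surf = np.zeros(minlength, dtype=np.int64)
    a = sites[:, :-1]
    b = sites[:, 1:]
    m = a != b
    surf += np.bincount(a[m], minlength=minlength)[:minlength]
    surf += np.bincount(b[m], minlength=minlength)[:minlength]
    a = sites[:-1, :]
    b = sites[1:, :]
    m = a != b
    surf += np.bincount(a[m], minlength=minlength)[:minlength]
    surf += np.bincount(b[m], minlength=minlength)[:minlength]
    return surf


# --------------------------------------------------------------------- energy
def total_energy(state: CpmState, params: SimulationParams) -> float:
    """Full from-scratch evaluation of the effective energy (pure function).

    Volumes, surfaces and centers of mass are recomputed from the lattice so
    this serves as an independent oracle for the incremental kernel.
    """
    s = state.sites
    flat = s.ravel()
    if flat.max(initial=0) >= state.n_agents:
        raise BookkeepingError("unregistered agent index on lattice")
    J = params.adhesion.as_array()
    typ = state.typ
    e = 0.0
    # adhesion over unordered neighborhood pixel pairs (half-space offsets)
    adx, ady = _kernel.neighbor_offsets(params.adhesion_neighbor_order)
    half = [(int(dy), int(dx)) for dx, dy in zip(adx, ady)
            if dy > 0 or (dy == 0 and dx > 0)]  # one of each +-offset pair
    for dy, dx in half:
        a = s[max(0, -dy):s.shape[0] - max(0, dy) or None,
              max(0, -dx):s.shape[1] - max(0, dx) or None]
        b = s[max(0, dy):s.shape[0] - max(0, -dy) or None,
              max(0, dx):s.shape[1] - max(0, -dx) or None]
        m = a != b
        e += J[typ[a[m]], typ[b[m]]].sum()
    # volume + surface terms from recomputed bookkeeping
    n = state.n_agents
    vol = np.bincount(flat, minlength=n)[:n].astype(float)
    surf = compute_surfaces(s, n).astype(float)
    # every registered agent is penalized, including one whose last pixel
    # was copied away (V = 0 keeps paying lambda_V*V_t^2, which is what makes
    # spontaneous cell annihilation prohibitively expensive); agents retired
    # by the event layer have their targets zeroed and contribute nothing
    idx = np.arange(1, n)
    e += float(np.sum(state.lam_v[idx] * (vol[idx] - state.vt[idx]) ** 2))
    e += float(np.sum(state.lam_s[idx] * (surf[idx] - state.st[idx]) ** 2))
    # spring links
    Y, X = np.mgrid[0:state.height, 0:state.width]
    sx = np.bincount(flat, weights=X.ravel(), minlength=n)[:n]
    sy = np.bincount(flat, weights=Y.ravel(), minlength=n)[:n]
    for a, b, lam, L in state.iter_links():
        ax, ay = sx[a] / vol[a], sy[a] / vol[a]
        bx, by = sx[b] / vol[b], sy[b] / vol[b]
        l_ij = float(np.hypot(ax - bx, ay - by))
        e += lam * (l_ij - L) ** 2
    return float(e)


def delta_energy(state: CpmState, params: SimulationParams,
                 target_yx: tuple[int, int], source_index: int) -> float:
    """Exact change in total_energy if the target pixel were overwritten
    with ``source_index``, computed incrementally."""
    ty, tx = target_yx
    if not (0 < ty < state.height - 1 and 0 < tx < state.width - 1):
        raise ValueError("target pixel must lie inside the immutable frame")
    adx, ady = _kernel.neighbor_offsets(params.adhesion_neighbor_order)
    return float(_kernel.delta_h_at(
        state.sites, state.typ, state.vol, state.surf, state.vt, state.st,
        state.lam_v, state.lam_s, state.sum_x, state.sum_y,
        state.link_partner, state.link_lam, state.link_len,
        params.adhesion.as_array(), adx, ady, ty, tx, np.int32(source_index)))


def metropolis_attempt(state: CpmState, params: SimulationParams,
                       rng: np.random.Generator) -> bool:
    """One pixel-copy attempt: accept with probability min(1, exp(-dH/T))."""
    ty = int(rng.integers(1, state.height - 1))
    tx = int(rng.integers(1, state.width - 1))
    k = int(rng.integers(8))
    b = state.sites[ty + _kernel._DY8[k], tx + _kernel._DX8[k]]
    a = state.sites[ty, tx]
    if a == b:
        return True
    dh = delta_energy(state, params, (ty, tx), b)
    if dh <= 0.0 or rng.random() < np.exp(-dh / params.temperature):
        _kernel.apply_copy(state.sites, state.vol, state.surf,
                           state.sum_x, state.sum_y, state.link_partner,
                           state.link_lam, state.link_len, ty, tx, np.int32(b))
        return True
    return False


_default_rng_state = _kernel.make_rng_state(0)


def seed_kernel(seed: int) -> np.ndarray:
    """Return a fresh kernel RNG state for ``seed`` (and reset the module
    default, used when ``run_mcs`` is called without an explicit state)."""
    global _default_rng_state
    _default_rng_state = _kernel.make_rng_state(int(seed) % (2 ** 31))
    return _default_rng_state


def run_mcs(state: CpmState, params: SimulationParams, n: int,
            hooks=(), mcs_offset: int = 0, rng_state: np.ndarray | None = None) -> int:
    """Advance the system by ``n`` Monte Carlo steps.

    One MCS = one copy attempt per lattice pixel.  After each MCS every hook
    is called as ``hook(state, mcs)`` with the 1-based step count (the event
    layer registers its death checks and mitosis schedule here).  Returns the
    total number of accepted attempts.
    """
    J = params.adhesion.as_array()
    adx, ady = _kernel.neighbor_offsets(params.adhesion_neighbor_order)
    n_attempts = state.width * state.height
    if rng_state is None:
        rng_state = _default_rng_state
    accepted = 0
    for i in range(int(n)):
        accepted += _kernel.run_one_mcs(
            state.sites, state.typ, state.vol, state.surf, state.vt, state.st,
            state.lam_v, state.lam_s, state.sum_x, state.sum_y,
            state.link_partner, state.link_lam, state.link_len,
            J, adx, ady, params.temperature, n_attempts, rng_state)
        mcs = mcs_offset + i + 1
        for hook in hooks:
            hook(state, mcs)
    return accepted


# ---------------------------------------------------------------------- links
def rebuild_links(state: CpmState, params: SimulationParams) -> None:
    """Re-derive the spring-link sets from current centers of mass.

    Two junction classes exist per agent, mirroring the per-type-pair
    junction cap of focal-point plasticity: up to two *lateral* links to
    same-layer neighbors (the polarity chain along each monolayer) and up to
    two *cross-layer* links tethering the luminal layer to the
    myoepithelium.  In each class an agent nominates its two nearest
    eligible partners and a link forms when the nomination is mutual.
    Medium and necrotic agents never participate.

    This full re-derivation is used at initialization (and in tests);
    during a run links persist and are maintained incrementally by
    :func:`maintain_links`.
    """
    state.link_partner[:state.n_agents] = -1
    state.link_lam[:state.n_agents] = 0.0
    state.link_len[:state.n_agents] = 0.0
    lep = state.live_indices(types=LEP)
    mep = state.live_indices(types=MEP)
    # lateral chains
    for members in (lep, mep):
        _mutual_pairs(state, params, members, members, slot_base=0)
    # cross-layer tethers
    _mutual_pairs(state, params, lep, mep, slot_base=2)


def _mutual_pairs(state: CpmState, params: SimulationParams,
                  group_a: np.ndarray, group_b: np.ndarray,
                  slot_base: int) -> None:
    """Link mutually-nearest nominations between two groups (which may be
    the same group) into slots [slot_base, slot_base + 1]."""
    if len(group_a) == 0 or len(group_b) == 0:
        return
    same = group_a is group_b
    if same and len(group_a) < 2:
        return
    coms_a = state.coms(group_a)
    coms_b = coms_a if same else state.coms(group_b)
    tree = cKDTree(coms_b)
    k = min(len(group_b), 3 if same else 2)
    _, nbr = tree.query(coms_a, k=k)
    nbr = np.atleast_2d(nbr.reshape(len(group_a), -1))
    choice: dict[int, list[int]] = {}
    for row, a in enumerate(group_a):
        picks = []
        for j in range(k):
            b = group_b[nbr[row, j]]
            if b != a:
                picks.append(int(b))
            if len(picks) == 2:
                break
        choice[int(a)] = picks
    if same:
        reverse = choice
    else:  # nominations from group_b back into group_a
        reverse = {}
        tree_a = cKDTree(coms_a)
        kk = min(len(group_a), 2)
        _, nbr_b = tree_a.query(coms_b, k=kk)
        nbr_b = np.atleast_2d(nbr_b.reshape(len(group_b), -1))
        for row, b in enumerate(group_b):
            reverse[int(b)] = [int(group_a[nbr_b[row, j]]) for j in range(kk)]
    for a, picks in choice.items():
        for b in picks:
            if (same and b <= a) or a not in reverse.get(b, ()):
                continue
            lam, L = params.fpp.spring(state.typ[a], state.typ[b])
            if lam != 0.0:
                _set_link(state, a, b, lam, L, slot_base)


LINK_FORMATION_RADIUS = 15.0  # px: centers within 1.5 cell diameters touch
LINK_BREAK_RADIUS = 25.0      # px: links detach once partners drift apart


def maintain_links(state: CpmState, params: SimulationParams,
                   formation_radius: float = LINK_FORMATION_RADIUS,
                   break_radius: float = LINK_BREAK_RADIUS) -> None:
    """Incremental link upkeep between full rebuilds.

    Existing links persist (they are focal adhesions, not re-optimized
    springs): a link only dissolves when its partners drift beyond the
    break radius.  Agents with a free slot in a junction class then pair
    with the nearest eligible agent that also has a free slot in that class
    and lies within the formation radius (links form on contact), closest
    pairs first.
    """
    # dissolve overstretched links (vectorized over the link list)
    n = state.n_agents
    lp = state.link_partner[:n]
    a_idx, s_idx = np.nonzero(lp > np.arange(n, dtype=lp.dtype)[:, None])
    if len(a_idx):
        b_idx = lp[a_idx, s_idx].astype(int)
        va = state.vol[a_idx].astype(float)
        vb = state.vol[b_idx].astype(float)
        dx = state.sum_x[a_idx] / va - state.sum_x[b_idx] / vb
        dy = state.sum_y[a_idx] / va - state.sum_y[b_idx] / vb
        too_far = np.hypot(dx, dy) > break_radius
        for a, b in zip(a_idx[too_far], b_idx[too_far]):
            _drop_link(state, int(a), int(b))
    # form new links on contact, closest pairs first, per junction class
    lep = state.live_indices(types=LEP)
    mep = state.live_indices(types=MEP)
    for group_a, group_b, base in ((lep, lep, 0), (mep, mep, 0), (lep, mep, 2)):
        _form_contacts(state, params, group_a, group_b, base, formation_radius)


def _form_contacts(state: CpmState, params: SimulationParams,
                   group_a: np.ndarray, group_b: np.ndarray,
                   slot_base: int, radius: float) -> None:
    same = group_a is group_b
    sl = slice(slot_base, slot_base + 2)
    free_a = group_a[(state.link_partner[group_a, sl] < 0).any(axis=1)]
    free_b = free_a if same else \
        group_b[(state.link_partner[group_b, sl] < 0).any(axis=1)]
    if len(free_a) == 0 or len(free_b) == 0 or (same and len(free_a) < 2):
        return
    coms_a = state.coms(free_a)
    if same:
        pairs = cKDTree(coms_a).query_pairs(radius, output_type="ndarray")
        if len(pairs) == 0:
            return
        cand = np.column_stack([free_a[pairs[:, 0]], free_a[pairs[:, 1]]])
        d = np.linalg.norm(coms_a[pairs[:, 0]] - coms_a[pairs[:, 1]], axis=1)
    else:
        coms_b = state.coms(free_b)
        hits = cKDTree(coms_b).query_ball_point(coms_a, radius)
        cand_list = [(int(free_a[i]), int(free_b[j]),
                      float(np.hypot(*(coms_a[i] - coms_b[j]))))
                     for i, js in enumerate(hits) for j in js]
        if not cand_list:
            return
        cand = np.array([(a, b) for a, b, _ in cand_list], dtype=int)
        d = np.array([x for _, _, x in cand_list])
    for i in np.argsort(d, kind="stable"):
        a, b = int(cand[i, 0]), int(cand[i, 1])
        if (state.link_partner[a, sl] < 0).any() and \
           (state.link_partner[b, sl] < 0).any() and \
           b not in state.link_partner[a]:
            lam, L = params.fpp.spring(state.typ[a], state.typ[b])
            if lam != 0.0:
                _set_link(state, a, b, lam, L, slot_base)


def _drop_link(state: CpmState, a: int, b: int) -> None:
    for e, p in ((a, b), (b, a)):
        for s in range(4):
            if state.link_partner[e, s] == p:
                state.link_partner[e, s] = -1
                state.link_lam[e, s] = 0.0
                state.link_len[e, s] = 0.0
                break


def _set_link(state: CpmState, a: int, b: int, lam: float, L: float,
              slot_base: int | None = None) -> None:
    if slot_base is None:
        slot_base = 0 if state.typ[a] == state.typ[b] else 2
    for e, p in ((a, b), (b, a)):
        for s in range(slot_base, slot_base + 2):
            if state.link_partner[e, s] < 0:
                state.link_partner[e, s] = p
                state.link_lam[e, s] = lam
                state.link_len[e, s] = L
                break
        else:  # pragma: no cover - nomination rules cap links per class at 2
            raise BookkeepingError(
                f"agent {e} already holds two links in this class")
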