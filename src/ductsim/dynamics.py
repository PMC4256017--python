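"""Biological event layer: mitosis, apoptosis, and necrosis.

These rules run once per MCS on top of the Metropolis dynamics:

* **Mitosis** — at a fixed cadence, a quarter of the live LEP are chosen at
  random and each is bisected by a straight cut through its center of mass.
  The cut orientation is set by the division-axis mode relative to the local
  layer normal (the radial direction from the duct's medial axis):
  ``perpendicular`` keeps the daughter within the layer, ``parallel`` pushes
  the daughter toward the lumen, ``random`` is isotropic.  Daughters enter at
  full target volume and regrow via the volume constraint.
* **Apoptosis** — a LEP with >= 10 other cells within 2.5 cell diameters
  (center-of-mass distance) is overcrowded; each overcrowded LEP is removed
  with a per-check probability (0-1%), its pixels reverting to medium.
* **Necrosis** — a LEP whose center of mass lies >= 10 cell diameters
  (100 px, roughly the oxygen diffusion limit) from the nearest MEP pixel
  becomes necrotic: it stops adhering and linking but keeps occupying space.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .engine import CpmState, maintain_links
from .geometry import Geometry
from .params import LEP, MEP, NECROTIC, SimulationParams

log = logging.getLogger(__name__)


# ----------------------------------------------------------------- selection
def select_mitotic_cells(state: CpmState, params: SimulationParams,
                         geometry: Geometry,
                         rng: np.random.Generator) -> np.ndarray:
    """Sample ceil(fraction * #LEP) live LEP indices without replacement.

    With preferential end proliferation enabled, cells whose center of mass
    lies in an end region carry twice the sampling weight of duct cells
    (weighted reservoir sampling via exponential keys), mimicking the ~2x
    division frequency observed at engineered-tissue ends.
    """
    lep = state.live_indices(types=LEP)
    if len(lep) == 0:
        return np.empty(0, dtype=int)
    k = math.ceil(params.mitotic_fraction * len(lep))
    if params.preferential_end_proliferation:
        regions = geometry.region_of_points(state.coms(lep))
        w = np.where(regions == 2, params.end_weight_factor, 1.0)
    else:
        w = np.ones(len(lep))
    keys = rng.random(len(lep)) ** (1.0 / w)
    order = np.argsort(keys)[::-1]
    return lep[order[:k]]


# ------------------------------------------------------------------ division
def divide_cell(state: CpmState, params: SimulationParams, sigma: int,
                geometry: Geometry, rng: np.random.Generator,
                pixels: tuple[np.ndarray, np.ndarray] | None = None,
                refresh: bool = True, warn: bool = True) -> int | None:
    """Bisect agent ``sigma`` through its center of mass; return the daughter
    index (or None if the cell is too small to divide).

    The daughter inherits the parent's type and constraint targets.  In
    ``parallel`` mode the luminal-side half becomes the daughter and, when
    luminal-progeny protection is enabled, is exempted from apoptosis checks.
    """
    if pixels is None:
        ys, xs = np.nonzero(state.sites == sigma)
    else:
        ys, xs = pixels
    if len(xs) < 2:
        if warn:
            log.warning("division skipped: agent %d has volume %d",
                        sigma, len(xs))
        return None
    cx, cy = xs.mean(), ys.mean()
    r_hat = geometry.radial_direction((cx, cy))
    mode = params.division_axis
    if mode == "perpendicular":
        # cleavage plane contains the radial direction -> split tangentially
        n = np.array([-r_hat[1], r_hat[0]])
    elif mode == "parallel":
        # cleavage plane contains the tangent -> split radially
        n = r_hat
    elif mode == "random":
        theta = rng.uniform(0.0, 2.0 * np.pi)
        n = np.array([np.cos(theta), np.sin(theta)])
    else:
        raise ValueError(f"unknown division axis {mode!r}")
    d = (xs - cx) * n[0] + (ys - cy) * n[1]
    if mode == "parallel":
        daughter_mask = d < 0  # the inner (luminal) side becomes the daughter
    else:
        daughter_mask = d > 0
    if daughter_mask.all() or not daughter_mask.any():
        # degenerate cut (e.g. a 1-px-thin cell): split by rank instead
        daughter_mask = d <= np.median(d)
        if daughter_mask.all():
            daughter_mask[np.argmax(d)] = False
    daughter = state.new_cell(state.typ[sigma], params)
    state.typ[daughter] = state.typ[sigma]
    state.vt[daughter] = state.vt[sigma]
    state.st[daughter] = state.st[sigma]
    state.lam_v[daughter] = state.lam_v[sigma]
    state.lam_s[daughter] = state.lam_s[sigma]
    if mode == "parallel" and params.protect_luminal_progeny:
        state.protected[daughter] = True
    else:
        state.protected[daughter] = state.protected[sigma]
    state.sites[ys[daughter_mask], xs[daughter_mask]] = daughter
    if refresh:
        state.refresh()
    return daughter


def _grouped_pixels(sites: np.ndarray, selected: np.ndarray, n_agents: int):
    """One-pass pixel lists for each selected agent: {sigma: (ys, xs)}."""
    lookup = np.zeros(n_agents, dtype=bool)
    lookup[selected] = True
    flat = sites.ravel()
    pos = np.flatnonzero(lookup[flat])
    vals = flat[pos]
    order = np.argsort(vals, kind="stable")
    pos = pos[order]
    vals = vals[order]
    W = sites.shape[1]
    groups = {}
    for sigma, start, stop in zip(*_runs(vals)):
        p = pos[start:stop]
        groups[int(sigma)] = (p // W, p % W)
    return groups


def _runs(vals: np.ndarray):
    if len(vals) == 0:
        return np.empty(0, int), np.empty(0, int), np.empty(0, int)
    change = np.flatnonzero(np.diff(vals)) + 1
    starts = np.concatenate([[0], change])
    stops = np.concatenate([change, [len(vals)]])
    return vals[starts], starts, stops


def mitosis_event(state: CpmState, params: SimulationParams,
                  geometry: Geometry, rng: np.random.Generator,
                  event_log: list | None = None, mcs: int = 0) -> list[int]:
    """One scheduled mitotic event; returns the new daughter indices."""
    selected = select_mitotic_cells(state, params, geometry, rng)
    daughters = []
    skipped = 0
    groups = _grouped_pixels(state.sites, selected, state.n_agents)
    for sigma in selected:
        px = groups.get(int(sigma))
        if px is None:
            continue
        d = divide_cell(state, params, int(sigma), geometry, rng,
                        pixels=px, refresh=False, warn=False)
        if d is None:
            skipped += 1
        elif d is not None:
            daughters.append(d)
            if event_log is not None:
                x, y = px[1].mean(), px[0].mean()
                event_log.append(dict(mcs=mcs, event="mitosis", sigma=int(sigma),
                                      daughter=d, x=float(x), y=float(y)))
    if skipped:
        log.warning("mitosis at MCS %d: %d of %d selected cells too small "
                    "to divide", mcs, skipped, len(selected))
    if daughters:
        state.refresh()
    return daughters


# ----------------------------------------------------------------- apoptosis
def crowding_counts(state: CpmState, params: SimulationParams) -> tuple[np.ndarray, np.ndarray]:
    """For each live LEP, the number of *other* live LEP within the
    overcrowding radius, COM-to-COM.

    Only the luminal epithelial population is counted: crowding-induced
    extrusion is an epithelial-sheet phenomenon, and counting the enclosing
    myoepithelium would mark the intact bilayer itself as overcrowded.
    Necrotic debris and medium never count.  Returns (lep_indices, counts).
    """
    lep = state.live_indices(types=LEP)
    if len(lep) == 0:
        return lep, np.zeros(0, dtype=int)
    tree = cKDTree(state.coms(lep))
    counts = tree.query_ball_point(state.coms(lep), params.overcrowding_radius,
                                   return_length=True)
    counts = np.asarray(counts, dtype=int) - 1  # each LEP is its own neighbor
    return lep, counts


def apoptosis_check(state: CpmState, params: SimulationParams,
                    rng: np.random.Generator,
                    event_log: list | None = None, mcs: int = 0) -> list[int]:
    """Remove each overcrowded, unprotected LEP with the configured
    probability; removed cells leave the lattice immediately."""
    p = params.apoptosis_probability
    if p <= 0.0:
        return []
    lep, counts = crowding_counts(state, params)
    crowded = lep[counts >= params.overcrowding_threshold]
    if len(crowded) == 0:
        return []
    crowded = crowded[~state.protected[crowded]]
    if len(crowded) == 0:
        return []
    dies = crowded[rng.random(len(crowded)) < p]
    for sigma in dies:
        if event_log is not None:
            x, y = state.com(sigma)
            event_log.append(dict(mcs=mcs, event="apoptosis", sigma=int(sigma),
                                  x=float(x), y=float(y)))
        state.remove_agent(int(sigma))
    if len(dies):
        state.refresh()  # neighbors' surfaces change when pixels revert to medium
    return [int(s) for s in dies]


# ------------------------------------------------------------------ necrosis
def necrosis_check(state: CpmState, params: SimulationParams,
                   event_log: list | None = None, mcs: int = 0) -> list[int]:
    """Convert to NECROTIC every LEP whose center of mass is at least the
    necrosis distance from the nearest MEP pixel (boundary inclusive)."""
    lep = state.live_indices(types=LEP)
    if len(lep) == 0:
        return []
    mep = state.live_indices(types=MEP)
    if len(mep) == 0:
        log.warning("necrosis check skipped: no MEP layer remains")
        return []
    lep_coms = state.coms(lep)
    # cheap prescreen on MEP centers of mass: the distance to the nearest MEP
    # pixel is at least the distance to its center minus one cell diameter
    d_com = cKDTree(state.coms(mep)).query(lep_coms)[0]
    candidates = lep[d_com >= params.necrosis_distance - 15.0]
    if len(candidates) == 0:
        return []
    mep_mask = state.typ[state.sites] == MEP
    dist = ndimage.distance_transform_edt(~mep_mask)
    coms = state.coms(candidates)
    ix = np.clip(np.rint(coms[:, 0]).astype(int), 0, state.width - 1)
    iy = np.clip(np.rint(coms[:, 1]).astype(int), 0, state.height - 1)
    newly = candidates[dist[iy, ix] >= params.necrosis_distance]
    for sigma in newly:
        state.typ[sigma] = NECROTIC
        state.clear_links(int(sigma))
        if event_log is not None:
            x, y = state.com(sigma)
            event_log.append(dict(mcs=mcs, event="necrosis", sigma=int(sigma),
                                  x=float(x), y=float(y)))
    return [int(s) for s in newly]


# --------------------------------------------------------------------- hooks
@dataclass
class DynamicsEngine:
    """Per-MCS hook bundling the event schedule and death rules.

    Register via ``engine.run_mcs(state, params, n, hooks=[dyn.hook])``.
    Link sets are rebuilt whenever topology changed and periodically
    otherwise (every MCS for small tissues; at a coarser cadence once the
    cell count makes the nearest-neighbor search the dominant cost).
    """

    state: CpmState
    params: SimulationParams
    geometry: Geometry
    rng: np.random.Generator
    event_log: list = field(default_factory=list)

    def hook(self, state: CpmState, mcs: int) -> None:
        p = self.params
        changed = False
        if p.mitosis_interval > 0 and mcs % p.mitosis_interval == 0:
            changed |= bool(mitosis_event(state, p, self.geometry, self.rng,
                                          self.event_log, mcs))
        changed |= bool(apoptosis_check(state, p, self.rng, self.event_log, mcs))
        changed |= bool(necrosis_check(state, p, self.event_log, mcs))
        # links persist; upkeep (breakage + contact formation) runs after any
        # topology change and periodically in between, at a coarser cadence
        # for very large cell counts where the neighbor search dominates
        n_cells = int(np.count_nonzero(state.vol[1:state.n_agents]))
        cadence = 1 if n_cells <= 1500 else 5
        if changed or mcs % cadence == 0:
            maintain_links(state, p)
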