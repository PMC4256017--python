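"""Snapshot classification into DCIS morphologies and invasion scoring.

The four histological morphologies are operationalized on the lattice:

* **normal** — a patent lumen with every LEP still part of the monolayer.
* **micropapillary** — extra LEP inside the lumen (agents with no MEP
  contact) while the lumen remains patent.
* **cribriform** — the duct is filled with cells forming >= 2 lumena, with
  an LEP bridge extending completely across the duct (an 8-connected LEP
  path between two wall cells whose connecting chord passes within half a
  lumen radius of the duct's medial axis).
* **solid** — no patent lumen remains (enclosed medium below one cell area).
* **comedo** — solid with a necrotic core.

The cascade is evaluated in the order comedo > solid > cribriform >
micropapillary > normal, mirroring the progression narrative (later stages
dominate the label).  ``classify`` is a pure function of the snapshot.

Invasion: a live LEP whose center of mass lies beyond the initial tissue
periphery dilated by one cell diameter.  Gaps in the MEP layer without LEP
extending past the periphery are counted as breaches, not invasion.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .engine import CpmState
from .geometry import Geometry
from .params import LEP, MEP, NECROTIC

MIN_LUMEN_AREA = 50.0   # px: sub-half-cell medium pockets are lattice noise
SOLID_LUMEN_AREA = 78.5  # px: less than one cell area of lumen = filled duct
PERIPHERY_DILATION = 10  # px: one cell diameter

_FOUR = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)
_EIGHT = np.ones((3, 3), dtype=bool)

VERDICTS = ("normal", "micropapillary", "cribriform", "solid", "comedo", "mixed")
# severity used for progression ordering; solid and comedo share a grade
SEVERITY = {"normal": 0, "micropapillary": 1, "cribriform": 2,
            "solid": 3, "comedo": 3}


@dataclass(frozen=True)
class Snapshot:
    """Immutable view of a simulation state at one MCS."""

    mcs: int
    sites: np.ndarray
    typ: np.ndarray           # per-agent type codes
    vol: np.ndarray
    coms: np.ndarray          # (n_agents, 2) float; NaN where volume is 0
    geometry: Geometry

    @classmethod
    def from_state(cls, state: CpmState, geometry: Geometry, mcs: int = 0):
        n = state.n_agents
        coms = np.full((n, 2), np.nan)
        live = state.vol[:n] > 0
        live[0] = False
        v = state.vol[:n][live].astype(float)
        coms[live, 0] = state.sum_x[:n][live] / v
        coms[live, 1] = state.sum_y[:n][live] / v
        return cls(mcs=mcs, sites=state.sites.copy(), typ=state.typ[:n].copy(),
                   vol=state.vol[:n].copy(), coms=coms, geometry=geometry)

    def live_of_type(self, t: int) -> np.ndarray:
        idx = np.arange(1, len(self.typ))
        return idx[(self.vol[idx] > 0) & (self.typ[idx] == t)]


@dataclass
class MorphologyLabel:
    verdict: str
    lumen_count: int = 0
    lumen_area: float = 0.0
    lumen_area_fraction: float = 0.0
    luminal_lep_count: int = 0
    necrotic_count: int = 0
    spanning_bridge: bool = False
    cribriform_with_necrosis: bool = False


@dataclass
class InvasionReport:
    end: bool = False
    duct: bool = False
    breach_count: int = 0
    invaders: list = field(default_factory=list)

    @property
    def any(self) -> bool:
        return self.end or self.duct


# ------------------------------------------------------------------- lumena
def segment_lumena(snapshot: Snapshot) -> list[tuple[np.ndarray, float]]:
    """Connected medium components enclosed by the tissue (4-connectivity,
    complementary to the 8-connected cell bodies), at least half a cell in
    area.  Returns [(mask, area), ...]."""
    if len(snapshot.live_of_type(MEP)) == 0:
        raise ValueError("snapshot has no MEP layer")
    medium = snapshot.sites == 0
    lab, n = ndimage.label(medium, structure=_FOUR)
    if n == 0:
        return []
    exterior = lab[0, 0]  # the immutable frame is always medium
    out = []
    areas = np.bincount(lab.ravel())
    for comp in range(1, n + 1):
        if comp == exterior or areas[comp] < MIN_LUMEN_AREA:
            continue
        out.append((lab == comp, float(areas[comp])))
    return out


# ------------------------------------------------------------------ classify
def classify(snapshot: Snapshot) -> MorphologyLabel:
    """Label one snapshot (pure function; identical snapshots give identical
    labels)."""
    geom = snapshot.geometry
    lumena = segment_lumena(snapshot)
    lumen_area = float(sum(a for _, a in lumena))
    initial_lumen = geom.initial_interior & ~geom.initial_footprint
    lumen_fraction = lumen_area / max(1.0, float(initial_lumen.sum()))
    necrotic = snapshot.live_of_type(NECROTIC)
    luminal = _luminal_lep(snapshot)
    filled = lumen_area < SOLID_LUMEN_AREA
    # the bridge search is the costly step; it can only decide the label for
    # an unfilled duct with multiple lumena
    bridge = (not filled and len(lumena) >= 2) and _spanning_bridge(snapshot)

    label = MorphologyLabel(verdict="normal", lumen_count=len(lumena),
                            lumen_area=lumen_area,
                            lumen_area_fraction=lumen_fraction,
                            luminal_lep_count=len(luminal),
                            necrotic_count=len(necrotic),
                            spanning_bridge=bridge)
    if filled and len(necrotic) > 0:
        label.verdict = "comedo"
    elif filled:
        label.verdict = "solid"
    elif len(lumena) >= 2 and bridge:
        label.verdict = "cribriform"
        label.cribriform_with_necrosis = len(necrotic) > 0
    elif len(luminal) >= 1:
        label.verdict = "micropapillary"
    return label


def _wall_contact_agents(snapshot: Snapshot) -> np.ndarray:
    """Live LEP agents with at least one pixel 8-adjacent to an MEP pixel."""
    typ_of_pixel = snapshot.typ[snapshot.sites]
    mep_zone = ndimage.binary_dilation(typ_of_pixel == MEP, structure=_EIGHT)
    touching = np.unique(snapshot.sites[mep_zone & (snapshot.sites > 0)])
    touching = touching[(touching > 0) & (snapshot.typ[touching] == LEP)]
    alive = touching[snapshot.vol[touching] > 0]
    return alive


def _luminal_lep(snapshot: Snapshot) -> np.ndarray:
    """Live LEP with no MEP contact whose center of mass still lies within
    the (dilated) tissue periphery — i.e. cells accumulated inside the duct,
    not invaders."""
    lep = snapshot.live_of_type(LEP)
    if len(lep) == 0:
        return lep
    wall = set(_wall_contact_agents(snapshot).tolist())
    free = np.array([a for a in lep if a not in wall], dtype=int)
    if len(free) == 0:
        return free
    outside = _beyond_periphery_mask(snapshot.geometry)
    coms = snapshot.coms[free]
    ix = np.clip(np.rint(coms[:, 0]).astype(int), 0, outside.shape[1] - 1)
    iy = np.clip(np.rint(coms[:, 1]).astype(int), 0, outside.shape[0] - 1)
    return free[~outside[iy, ix]]


_periphery_cache: dict[int, np.ndarray] = {}


def _beyond_periphery_mask(geom: Geometry) -> np.ndarray:
    """Pixels beyond the initial tissue outline dilated by one cell diameter."""
    key = id(geom)
    if key not in _periphery_cache:
        r = PERIPHERY_DILATION
        yy, xx = np.mgrid[-r:r + 1, -r:r + 1]
        disk = xx ** 2 + yy ** 2 <= r ** 2
        dilated = ndimage.binary_dilation(geom.initial_interior, structure=disk)
        _periphery_cache.clear()  # geometries are per-run; keep the cache tiny
        _periphery_cache[key] = ~dilated
    return _periphery_cache[key]


def _spanning_bridge(snapshot: Snapshot) -> bool:
    """True when luminal LEP (cells off the wall) form an 8-connected band
    anchored to the monolayer at two wall cells whose center-to-center chord
    passes within half a lumen radius of the duct's medial axis — i.e.
    "cells extended completely across the diameter".

    Paths running along the monolayer itself never qualify: only components
    of non-wall LEP can carry a bridge, and their two anchors must lie on
    opposite sides of the duct.
    """
    geom = snapshot.geometry
    wall = _wall_contact_agents(snapshot)
    if len(wall) < 2:
        return False
    wall_set = np.zeros(len(snapshot.typ), dtype=bool)
    wall_set[wall] = True
    typ_of_pixel = snapshot.typ[snapshot.sites]
    luminal_mask = (typ_of_pixel == LEP) & ~wall_set[snapshot.sites]
    if not luminal_mask.any():
        return False
    lab, ncomp = ndimage.label(luminal_mask, structure=_EIGHT)
    threshold = geom.lumen_radius / 2.0
    wall_coms = snapshot.coms[wall]
    for c in range(1, ncomp + 1):
        comp_mask = lab == c
        if comp_mask.sum() < MIN_LUMEN_AREA:
            continue  # a sub-half-cell speck cannot span the duct
        touch = ndimage.binary_dilation(comp_mask, structure=_EIGHT)
        anchors = np.unique(snapshot.sites[touch])
        anchors = anchors[(anchors > 0) & wall_set[anchors]]
        if len(anchors) < 2:
            continue
        pts = snapshot.coms[anchors]
        if _chord_near_axis(pts, pts, geom, threshold):
            return True
    return False


def _chord_near_axis(pa: np.ndarray, pb: np.ndarray, geom: Geometry,
                     threshold: float) -> bool:
    """Does any chord between the two point sets pass within ``threshold``
    of the skeleton?  Chords are sampled at 17 interior points."""
    if len(pa) < 2:
        return False
    t = np.linspace(0.0, 1.0, 17)
    for i in range(len(pa)):
        seg = pa[i][None, None, :] + t[None, :, None] * (pb[:, None, :] - pa[i][None, None, :])
        pts = seg.reshape(-1, 2)
        d = geom.dist_to_skeleton(pts).reshape(len(pb), -1).min(axis=1)
        d[i] = np.inf  # a point is not a chord with itself
        if (d < threshold).any():
            return True
    return False


# ------------------------------------------------------------------ invasion
def _disk(r: int) -> np.ndarray:
    yy, xx = np.mgrid[-r:r + 1, -r:r + 1]
    return xx ** 2 + yy ** 2 <= r ** 2


def detect_invasion(snapshot: Snapshot) -> InvasionReport:
    """Score invasion: a live LEP whose center of mass lies beyond the
    tissue periphery, attributed to the end/duct region of its exit point.

    "Beyond the periphery" requires passing *both* envelopes: the initial
    tissue outline dilated by one cell diameter (so growth alone does not
    count immediately) and the current myoepithelial envelope — the MEP
    mask morphologically closed (sealing sub-cell-scale gaps), hole-filled,
    and dilated by one cell diameter. A proliferating duct that merely
    expands keeps its boundary cells inside the MEP envelope; gaps in the
    MEP without cells extending past the tissue outline count as breaches,
    never invasion."""
    geom = snapshot.geometry
    lep = snapshot.live_of_type(LEP)
    report = InvasionReport()
    if len(lep):
        outside_init = _beyond_periphery_mask(geom)
        mep_mask = snapshot.typ[snapshot.sites] == MEP
        if mep_mask.any():
            envelope = ndimage.binary_closing(mep_mask, structure=_disk(12))
            envelope = ndimage.binary_fill_holes(envelope)
            envelope = ndimage.binary_dilation(envelope,
                                               structure=_disk(PERIPHERY_DILATION))
            outside = outside_init & ~envelope
        else:
            outside = outside_init
        # cells that poke through the myoepithelium but remain part of the
        # cohesive tissue mass have not extended past its periphery; an
        # invading cell has moved out into the surroundings, i.e. belongs
        # to a cell component detached from the main mass
        cells = snapshot.sites > 0
        lab, ncomp = ndimage.label(cells, structure=_EIGHT)
        if ncomp > 1:
            main = int(np.argmax(np.bincount(lab[cells])[1:]) + 1)
            detached_sigma = np.unique(snapshot.sites[cells & (lab != main)])
        else:
            detached_sigma = np.empty(0, dtype=int)
        is_detached = np.zeros(len(snapshot.typ), dtype=bool)
        is_detached[detached_sigma] = True
        coms = snapshot.coms[lep]
        ix = np.clip(np.rint(coms[:, 0]).astype(int), 0, outside.shape[1] - 1)
        iy = np.clip(np.rint(coms[:, 1]).astype(int), 0, outside.shape[0] - 1)
        out = outside[iy, ix] & is_detached[lep]
        invaders = lep[out]
        if len(invaders):
            regions = geom.region_of_points(snapshot.coms[invaders])
            report.end = bool((regions == 2).any())
            report.duct = bool((regions == 1).any())
            report.invaders = [int(a) for a in invaders]
    report.breach_count = _count_breaches(snapshot)
    return report


def _count_breaches(snapshot: Snapshot) -> int:
    """Number of corridors through the MEP layer connecting the exterior to
    the tissue body (gaps in the myoepithelium, invasive or not)."""
    typ_of_pixel = snapshot.typ[snapshot.sites]
    non_mep = typ_of_pixel != MEP
    lab, _ = ndimage.label(non_mep, structure=_FOUR)
    exterior = lab == lab[0, 0]
    filled = ndimage.binary_fill_holes(snapshot.sites > 0)
    corridors = exterior & filled
    _, n = ndimage.label(corridors, structure=_FOUR)
    return int(n)


# ----------------------------------------------------------------- consensus
def classify_replicates(labels: list[MorphologyLabel | str],
                        threshold: float = 0.8) -> str:
    """Modal verdict across replicate snapshots if its frequency reaches the
    consensus threshold (80%), else ``"mixed"``."""
    if not labels:
        raise ValueError("need at least one label")
    verdicts = [l.verdict if isinstance(l, MorphologyLabel) else l for l in labels]
    word, count = Counter(verdicts).most_common(1)[0]
    return word if count / len(verdicts) >= threshold else "mixed"
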