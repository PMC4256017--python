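"""Initial tissue construction for the three duct archetypes.

All archetypes share one recipe: a *skeleton* (a point for the circular
cross-section; one segment for the cylinder; three segments for the
bifurcation) defines a distance field.  Pixels closer than the lumen radius
are lumen (medium); the next 10 px band is the luminal epithelial (LEP)
monolayer; the band beyond that is the myoepithelial (MEP) monolayer.  Each
band is partitioned into ~10 px wide cells by Voronoi assignment to seed
points spaced evenly along the band's centerline contour, which guarantees a
watertight (closed) monolayer at initialization.  Cells start as these
compact lattice sectors and round up within a few MCS under the
volume/surface constraints.

The geometry also owns the end/duct region rule used in invasion scoring:
a location belongs to an *end* region when its projection onto the skeleton
lies within the end-cap depth of a skeleton tip.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure

from .engine import CpmState
from .params import CELL_DIAMETER, LEP, MEP, SimulationParams

LAYER_PX = 10  # monolayer thickness: one cell diameter


@dataclass
class TissueBlueprint:
    """Construction parameters for an initial duct."""

    archetype: str = "circle"        # 'circle' | 'cylinder' | 'bifurcation'
    lumen_radius: float = 75.0       # circle default: 50 LEP of 10 px around it
    n_lep: int | None = 50           # forced LEP count (circle); None = by spacing
    duct_length: float = 300.0       # straight length (cylinder, bifurcation trunk)
    branch_length: float = 150.0     # bifurcation branch length
    branch_angle_deg: float = 45.0
    cylinder_lumen_halfwidth: float = 25.0
    end_depth: float | None = None   # end-region depth; default = lumen diameter
    margin: float = 25.0             # medium margin around the tissue


@dataclass
class Geometry:
    """Static geometric context carried through a run (never mutated)."""

    blueprint: TissueBlueprint
    skeleton: np.ndarray             # (k, 2, 2) segments, (x, y) endpoints
    lumen_radius: float
    region_mask: np.ndarray          # uint8: 0 exterior, 1 duct, 2 end
    initial_footprint: np.ndarray    # bool: LEP+MEP pixels at MCS 0
    initial_interior: np.ndarray     # bool: footprint with lumen filled
    lumen_centroid: tuple[float, float]
    tips: np.ndarray = field(default_factory=lambda: np.zeros((0, 2)))

    def dist_to_skeleton(self, points: np.ndarray) -> np.ndarray:
        return _dist_to_segments(np.atleast_2d(points), self.skeleton)[0]

    def nearest_skeleton_point(self, points: np.ndarray) -> np.ndarray:
        return _dist_to_segments(np.atleast_2d(points), self.skeleton)[1]

    def radial_direction(self, point: tuple[float, float]) -> np.ndarray:
        """Unit vector from the local medial axis toward ``point`` (the layer
        normal used to orient division axes)."""
        p = np.asarray(point, dtype=float)
        q = self.nearest_skeleton_point(p[None, :])[0]
        v = p - q
        n = np.linalg.norm(v)
        if n < 1e-9:  # exactly on the axis: any direction serves
            return np.array([1.0, 0.0])
        return v / n

    def region_of_points(self, points: np.ndarray) -> np.ndarray:
        """1 = duct, 2 = end, for arbitrary (x, y) locations."""
        pts = np.atleast_2d(points)
        if len(self.tips) == 0:
            return np.ones(len(pts), dtype=np.uint8)
        proj = self.nearest_skeleton_point(pts)
        depth = self.blueprint.end_depth
        if depth is None:
            depth = 2.0 * self.lumen_radius
        d_tip = np.min(np.linalg.norm(proj[:, None, :] - self.tips[None, :, :],
                                      axis=2), axis=1)
        out = np.ones(len(pts), dtype=np.uint8)
        out[d_tip <= depth] = 2
        return out


def _dist_to_segments(points: np.ndarray, segments: np.ndarray):
    """Min distance (and nearest point) from each (x, y) point to a segment set."""
    best_d = np.full(len(points), np.inf)
    best_q = np.zeros_like(points, dtype=float)
    for seg in segments:
        a, b = seg[0], seg[1]
        ab = b - a
        denom = float(ab @ ab)
        if denom == 0.0:
            t = np.zeros(len(points))
        else:
            t = np.clip((points - a) @ ab / denom, 0.0, 1.0)
        q = a + t[:, None] * ab
        d = np.linalg.norm(points - q, axis=1)
        closer = d < best_d
        best_d[closer] = d[closer]
        best_q[closer] = q[closer]
    return best_d, best_q


def _build(blueprint: TissueBlueprint, params: SimulationParams,
           segments: np.ndarray, tips: np.ndarray,
           width: int, height: int) -> tuple[CpmState, Geometry]:
    state = CpmState(width, height)
    Y, X = np.mgrid[0:height, 0:width]
    pts = np.column_stack([X.ravel(), Y.ravel()]).astype(float)
    dist = _dist_to_segments(pts, segments)[0].reshape(height, width)

    r = blueprint.lumen_radius
    lep_band = (dist >= r) & (dist < r + LAYER_PX)
    mep_band = (dist >= r + LAYER_PX) & (dist < r + 2 * LAYER_PX)
    # keep the immutable frame clear
    frame = np.zeros((height, width), dtype=bool)
    frame[0, :] = frame[-1, :] = frame[:, 0] = frame[:, -1] = True
    if ((lep_band | mep_band) & frame).any():
        raise ValueError("lattice too small for the requested duct")

    for band, typ, forced_n in ((lep_band, LEP, blueprint.n_lep),
                                (mep_band, MEP, None)):
        seeds = _band_seeds(dist, r + (0.5 if typ == LEP else 1.5) * LAYER_PX,
                            forced_n)
        _assign_band(state, band, seeds, typ, params)

    state.refresh()
    footprint = state.sites > 0
    interior = ndimage.binary_fill_holes(footprint)
    region = np.zeros((height, width), dtype=np.uint8)
    geom = Geometry(blueprint=blueprint, skeleton=segments, lumen_radius=r,
                    region_mask=region, initial_footprint=footprint,
                    initial_interior=interior,
                    lumen_centroid=tuple(np.mean(segments.reshape(-1, 2), axis=0)),
                    tips=tips)
    labels = geom.region_of_points(pts).reshape(height, width)
    region[interior] = labels[interior]
    return state, geom


def _band_seeds(dist: np.ndarray, level: float, forced_n: int | None) -> np.ndarray:
    """Evenly spaced (x, y) seed points along the iso-distance contour."""
    contours = measure.find_contours(dist, level)
    if not contours:
        raise ValueError("no band centerline found; lattice too small?")
    loop = max(contours, key=len)  # the single closed loop around the skeleton
    xy = loop[:, ::-1]  # (row, col) -> (x, y)
    seg = np.linalg.norm(np.diff(xy, axis=0), axis=1)
    arclen = np.concatenate([[0.0], np.cumsum(seg)])
    total = arclen[-1]
    n = forced_n if forced_n else max(3, int(round(total / CELL_DIAMETER)))
    targets = np.linspace(0.0, total, n, endpoint=False)
    sx = np.interp(targets, arclen, xy[:, 0])
    sy = np.interp(targets, arclen, xy[:, 1])
    return np.column_stack([sx, sy])


def _assign_band(state: CpmState, band: np.ndarray, seeds: np.ndarray,
                 typ: int, params: SimulationParams) -> None:
    from scipy.spatial import cKDTree

    ys, xs = np.nonzero(band)
    owner = cKDTree(seeds).query(np.column_stack([xs, ys]))[1]
    indices = [state.new_cell(typ, params) for _ in range(len(seeds))]
    idx_map = np.asarray(indices, dtype=np.int32)
    state.sites[ys, xs] = idx_map[owner]


def init_circle(params: SimulationParams,
                blueprint: TissueBlueprint | None = None):
    """Circular duct cross-section: 50 LEP enclosed by an MEP ring.

    Returns ``(state, geometry)``; the region mask is all duct (a circle has
    no ends).
    """
    bp = blueprint or TissueBlueprint(archetype="circle")
    half = int(np.ceil(bp.lumen_radius + 2 * LAYER_PX + bp.margin))
    size = 2 * half
    c = half
    segments = np.array([[[c, c], [c, c]]], dtype=float)
    return _build(bp, params, segments, np.zeros((0, 2)), size, size)


def init_cylinder(params: SimulationParams,
                  blueprint: TissueBlueprint | None = None):
    """Longitudinal section through a cylindrical duct (a stadium-shaped
    bilayer): two parallel monolayer walls capped at both tips.

    Returns ``(state, geometry)``; the region mask labels both tip caps as
    end regions.
    """
    bp = blueprint or TissueBlueprint(archetype="cylinder",
                                      lumen_radius=25.0, n_lep=None)
    r = bp.lumen_radius
    outer = r + 2 * LAYER_PX
    width = int(np.ceil(bp.duct_length + 2 * outer + 2 * bp.margin))
    height = int(np.ceil(2 * outer + 2 * bp.margin))
    y0 = height / 2.0
    x0 = bp.margin + outer
    x1 = x0 + bp.duct_length
    segments = np.array([[[x0, y0], [x1, y0]]], dtype=float)
    tips = np.array([[x0, y0], [x1, y0]], dtype=float)
    return _build(bp, params, segments, tips, width, height)


def init_bifurcation(params: SimulationParams,
                     blueprint: TissueBlueprint | None = None):
    """Y-shaped duct: a trunk splitting into two branches.

    Returns ``(state, geometry)``; the three free tips are end regions.
    """
    bp = blueprint or TissueBlueprint(archetype="bifurcation",
                                      lumen_radius=25.0, n_lep=None,
                                      duct_length=150.0, branch_length=150.0)
    r = bp.lumen_radius
    outer = r + 2 * LAYER_PX
    ang = np.deg2rad(bp.branch_angle_deg)
    bl = bp.branch_length
    x_j = bp.margin + outer + bp.duct_length      # junction x
    dy = bl * np.sin(ang)
    dx = bl * np.cos(ang)
    height = int(np.ceil(2 * dy + 2 * outer + 2 * bp.margin))
    width = int(np.ceil(bp.duct_length + dx + 2 * outer + 2 * bp.margin))
    y0 = height / 2.0
    x0 = bp.margin + outer
    segments = np.array([
        [[x0, y0], [x_j, y0]],
        [[x_j, y0], [x_j + dx, y0 - dy]],
        [[x_j, y0], [x_j + dx, y0 + dy]],
    ], dtype=float)
    tips = np.array([[x0, y0], [x_j + dx, y0 - dy], [x_j + dx, y0 + dy]])
    return _build(bp, params, segments, tips, width, height)


def init_tissue(params: SimulationParams,
                blueprint: TissueBlueprint | None = None,
                archetype: str | None = None):
    """Dispatch on archetype name."""
    name = archetype or (blueprint.archetype if blueprint else "circle")
    builders = {"circle": init_circle, "cylinder": init_cylinder,
                "bifurcation": init_bifurcation}
    if name not in builders:
        raise KeyError(f"unknown archetype {name!r}")
    return builders[name](params, blueprint)
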