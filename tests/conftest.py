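"""Shared fixtures: tiny hand-built lattices and relaxed ducts."""

from __future__ import annotations

import numpy as np
import pytest

from ductsim import CpmState, SimulationParams, rebuild_links
from ductsim.params import LEP, MEP, NECROTIC


@pytest.fixture
def params() -> SimulationParams:
    return SimulationParams(seed=1)


@pytest.fixture
def two_cell_state(params) -> CpmState:
    """Two overlapping-range square cells (LEP + MEP) on a 20x20 lattice."""
    st = CpmState(20, 20)
    a = st.new_cell(LEP, params)
    b = st.new_cell(MEP, params)
    st.sites[5:12, 3:10] = a
    st.sites[8:16, 9:17] = b
    st.refresh()
    rebuild_links(st, params)
    return st


@pytest.fixture
def three_cell_state(params) -> CpmState:
    """Three well-separated square cells (2 LEP + 1 MEP) with spring links."""
    st = CpmState(30, 30)
    c1 = st.new_cell(LEP, params)
    c2 = st.new_cell(LEP, params)
    c3 = st.new_cell(MEP, params)
    st.sites[3:13, 3:13] = c1
    st.sites[3:13, 16:26] = c2
    st.sites[17:27, 8:18] = c3
    st.refresh()
    rebuild_links(st, params)
    return st


def random_cell_lattice(rng: np.random.Generator, size: int = 24,
                        n_cells: int = 4, params: SimulationParams | None = None,
                        link: bool = True) -> CpmState:
    """Random blobby multi-cell lattice for property tests."""
    params = params or SimulationParams()
    st = CpmState(size, size)
    centers = rng.integers(4, size - 4, size=(n_cells, 2))
    for i, (cx, cy) in enumerate(centers):
        typ = LEP if i % 2 == 0 else MEP
        idx = st.new_cell(typ, params)
        h = int(rng.integers(2, 5))
        w = int(rng.integers(2, 5))
        y0, y1 = max(1, cy - h), min(size - 1, cy + h)
        x0, x1 = max(1, cx - w), min(size - 1, cx + w)
        st.sites[y0:y1, x0:x1] = idx
    st.refresh()
    if link:
        rebuild_links(st, params)
    return st


def paint_disk(st: CpmState, cx: float, cy: float, r: float, idx: int) -> None:
    Y, X = np.mgrid[0:st.height, 0:st.width]
    st.sites[(X - cx) ** 2 + (Y - cy) ** 2 <= r ** 2] = idx


def ring_fixture(verdict: str = "normal", size: int = 140):
    """Hand-drawn duct snapshots for each morphology.

    A synthetic circular bilayer (MEP annulus enclosing an LEP annulus) with
    the interior arranged per the requested verdict.
    """
    from ductsim.geometry import Geometry, TissueBlueprint
    from ductsim.morphology import Snapshot
    from scipy import ndimage

    params = SimulationParams()
    st = CpmState(size, size)
    c = size / 2
    r_lumen = 35.0
    Y, X = np.mgrid[0:size, 0:size]
    rr = np.sqrt((X - c) ** 2 + (Y - c) ** 2)
    theta = np.arctan2(Y - c, X - c)

    def ring_cells(r0, r1, n, typ):
        band = (rr >= r0) & (rr < r1)
        sector = np.floor((theta + np.pi) / (2 * np.pi) * n).astype(int) % n
        ids = [st.new_cell(typ, params) for _ in range(n)]
        st.sites[band] = np.asarray(ids, dtype=np.int32)[sector[band]]
        return ids

    ring_cells(r_lumen, r_lumen + 10, 24, LEP)
    ring_cells(r_lumen + 10, r_lumen + 20, 30, MEP)

    if verdict == "micropapillary":
        for k in range(3):
            idx = st.new_cell(LEP, params)
            ang = 2 * np.pi * k / 3
            paint_disk(st, c + 20 * np.cos(ang), c + 20 * np.sin(ang), 5, idx)
    elif verdict in ("solid", "comedo", "cribriform"):
        # fill the lumen with a block of LEP cells on a coarse grid
        fill = rr < r_lumen
        gx = (X // 10) % 4
        gy = (Y // 10) % 4
        ids = np.array([[st.new_cell(LEP, params) for _ in range(4)]
                        for _ in range(4)], dtype=np.int32)
        st.sites[fill] = ids[gy[fill], gx[fill]]
        if verdict == "comedo":
            idx = st.new_cell(NECROTIC, params)
            paint_disk(st, c, c, 8, idx)
        if verdict == "cribriform":
            # carve two off-axis lumena through the fill
            st.sites[(X - (c - 18)) ** 2 + (Y - c) ** 2 <= 81] = 0
            st.sites[(X - (c + 18)) ** 2 + (Y - c) ** 2 <= 81] = 0
    st.refresh()

    footprint = st.sites > 0
    interior = ndimage.binary_fill_holes(footprint)
    geom = Geometry(blueprint=TissueBlueprint(archetype="circle",
                                              lumen_radius=r_lumen),
                    skeleton=np.array([[[c, c], [c, c]]], dtype=float),
                    lumen_radius=r_lumen,
                    region_mask=interior.astype(np.uint8),
                    initial_footprint=footprint,
                    initial_interior=interior,
                    lumen_centroid=(c, c))
    return Snapshot.from_state(st, geom, mcs=0), st, geom
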