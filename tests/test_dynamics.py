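"""Mitosis selection and division geometry, apoptosis, necrosis."""

import math

import numpy as np
import pytest

from ductsim import SimulationParams, init_circle
from ductsim.dynamics import (apoptosis_check, crowding_counts, divide_cell,
                              mitosis_event, necrosis_check,
                              select_mitotic_cells)
from ductsim.engine import CpmState
from ductsim.geometry import Geometry, TissueBlueprint
from ductsim.params import LEP, MEP, NECROTIC


def _point_geometry(cx=50.0, cy=50.0):
    """Minimal geometry whose medial axis is a single point (circle-like)."""
    seg = np.array([[[cx, cy], [cx, cy]]], dtype=float)
    dummy = np.zeros((100, 100), dtype=np.uint8)
    return Geometry(blueprint=TissueBlueprint(), skeleton=seg,
                    lumen_radius=35.0, region_mask=dummy,
                    initial_footprint=dummy.astype(bool),
                    initial_interior=dummy.astype(bool),
                    lumen_centroid=(cx, cy))


@pytest.fixture
def ring(params):
    """A relaxed 50-LEP circular duct."""
    state, geom = init_circle(params)
    return state, geom


class TestSelection:
    def test_ceiling_rule(self, ring, params):
        state, geom = ring
        rng = np.random.default_rng(0)
        chosen = select_mitotic_cells(state, params, geom, rng)
        n_lep = len(state.live_indices(types=LEP))
        assert n_lep == 50
        assert len(chosen) == math.ceil(0.25 * n_lep) == 13
        assert len(set(chosen.tolist())) == len(chosen)  # without replacement

    def test_no_lep_gives_empty_set(self, params):
        st = CpmState(20, 20)
        a = st.new_cell(MEP, params)
        st.sites[5:15, 5:15] = a
        st.refresh()
        out = select_mitotic_cells(st, params, _point_geometry(), np.random.default_rng(0))
        assert len(out) == 0

    def test_uniform_selection_frequency(self, ring, params):
        """Over many draws every LEP is selected at ~the same rate."""
        state, geom = ring
        rng = np.random.default_rng(1)
        lep = state.live_indices(types=LEP)
        hits = {int(a): 0 for a in lep}
        n_draws = 4000
        for _ in range(n_draws):
            for a in select_mitotic_cells(state, params, geom, rng):
                hits[int(a)] += 1
        rates = np.array(list(hits.values())) / n_draws
        assert rates.mean() == pytest.approx(13 / 50, abs=0.01)
        assert rates.min() > 0.26 - 0.05 and rates.max() < 0.26 + 0.05

    def test_end_cells_selected_at_twice_the_rate(self, params):
        """With preferential end proliferation and equal end/duct
        populations, end cells divide at ~2x the per-cell rate (+-10%)."""
        p = params.replace(preferential_end_proliferation=True)
        st = CpmState(210, 60)
        # 20 cells in the 'end' zone (near skeleton tip) and 20 in the duct
        seg = np.array([[[10.0, 30.0], [200.0, 30.0]]])
        dummy = np.zeros((60, 210), dtype=np.uint8)
        geom = Geometry(blueprint=TissueBlueprint(end_depth=50.0,
                                                  lumen_radius=25.0),
                        skeleton=seg, lumen_radius=25.0, region_mask=dummy,
                        initial_footprint=dummy.astype(bool),
                        initial_interior=dummy.astype(bool),
                        lumen_centroid=(105.0, 30.0),
                        tips=np.array([[10.0, 30.0]]))
        ids = []
        for i in range(40):
            idx = st.new_cell(LEP, p)
            x = 12 + 4 * i  # first 20 within 50+25 px of the tip... spread out
            st.sites[28:32, x:x + 3] = idx
            ids.append(idx)
        st.refresh()
        regions = geom.region_of_points(st.coms(np.array(ids)))
        end_ids = {i for i, r in zip(ids, regions) if r == 2}
        duct_ids = set(ids) - end_ids
        assert len(end_ids) >= 10 and len(duct_ids) >= 10
        rng = np.random.default_rng(2)
        end_hits = duct_hits = 0
        n_draws = 6000
        for _ in range(n_draws):
            sel = set(select_mitotic_cells(st, p, geom, rng).tolist())
            end_hits += len(sel & end_ids)
            duct_hits += len(sel & duct_ids)
        ratio = (end_hits / len(end_ids)) / (duct_hits / len(duct_ids))
        assert ratio == pytest.approx(2.0, rel=0.10)


class TestDivision:
    def test_symmetric_bisection_of_square(self, params):
        st = CpmState(30, 30)
        a = st.new_cell(LEP, params)
        st.sites[10:20, 10:20] = a
        st.refresh()
        geom = _point_geometry(cx=15.0, cy=60.0)  # radial dir is vertical
        d = divide_cell(st, params.replace(division_axis="parallel"), a, geom,
                        np.random.default_rng(0))
        assert d is not None
        assert st.vol[a] == 50 and st.vol[d] == 50

    def test_pixel_partition_conserves_volume(self, params):
        rng = np.random.default_rng(3)
        for mode in ("perpendicular", "parallel", "random"):
            st = CpmState(30, 30)
            a = st.new_cell(LEP, params)
            mask = rng.random((8, 11)) < 0.85
            st.sites[10:18, 8:19][mask] = a
            st.refresh()
            v0 = int(st.vol[a])
            p = params.replace(division_axis=mode)
            d = divide_cell(st, p, a, _point_geometry(15, 15), rng)
            assert d is not None
            assert int(st.vol[a]) + int(st.vol[d]) == v0

    def test_too_small_to_divide(self, params, caplog):
        st = CpmState(10, 10)
        a = st.new_cell(LEP, params)
        st.sites[5, 5] = a
        st.refresh()
        with caplog.at_level("WARNING"):
            assert divide_cell(st, params, a, _point_geometry(), np.random.default_rng(0)) is None
        assert "skipped" in caplog.text

    def test_perpendicular_mode_keeps_daughter_in_layer(self, ring, params):
        """In a circular duct, perpendicular division leaves the daughter at
        ~the parent's radius (tangential split: radial offset ~0)."""
        state, geom = ring
        rng = np.random.default_rng(4)
        center = np.asarray(geom.lumen_centroid)
        offsets_r, offsets_t = [], []
        for sigma in state.live_indices(types=LEP)[:25]:
            com0 = np.asarray(state.com(int(sigma)))
            d = divide_cell(state, params, int(sigma), geom, rng)
            assert d is not None
            com_d = np.asarray(state.com(d))
            r_hat = (com0 - center) / np.linalg.norm(com0 - center)
            delta = com_d - com0
            offsets_r.append(abs(delta @ r_hat))
            offsets_t.append(abs(delta @ np.array([-r_hat[1], r_hat[0]])))
        # radial offsets stay below half a cell width; tangential dominate
        assert np.mean(offsets_r) < 2.0
        assert np.mean(offsets_t) > np.mean(offsets_r)

    def test_parallel_mode_pushes_daughter_inward(self, ring, params):
        state, geom = ring
        p = params.replace(division_axis="parallel")
        rng = np.random.default_rng(5)
        center = np.asarray(geom.lumen_centroid)
        inward = 0
        cells = state.live_indices(types=LEP)[:20]
        for sigma in cells:
            com0 = np.asarray(state.com(int(sigma)))
            d = divide_cell(state, p, int(sigma), geom, rng)
            com_d = np.asarray(state.com(d))
            if np.linalg.norm(com_d - center) < np.linalg.norm(com0 - center):
                inward += 1
        assert inward == len(cells)

    def test_population_growth_recurrence(self, ring, params):
        """With no deaths, #LEP after k mitotic events follows the ceiling
        recurrence N <- N + ceil(N/4)."""
        state, geom = ring
        rng = np.random.default_rng(6)
        expected = 50
        for _ in range(4):
            mitosis_event(state, params, geom, rng)
            expected += math.ceil(expected / 4)
            assert len(state.live_indices(types=LEP)) == expected


class TestApoptosis:
    def test_zero_probability_removes_nothing(self, ring):
        state, geom = ring
        p = SimulationParams(apoptosis_probability=0.0)
        assert apoptosis_check(state, p, np.random.default_rng(0)) == []

    def test_crowding_counts_match_brute_force(self, ring, params):
        """KD-tree neighbor counts equal an O(n^2) all-pairs distance oracle."""
        state, geom = ring
        lep, counts = crowding_counts(state, params)
        coms = state.coms(lep)
        d = np.sqrt(((coms[:, None, :] - coms[None, :, :]) ** 2).sum(-1))
        brute = ((d <= params.overcrowding_radius).sum(axis=1) - 1)
        assert np.array_equal(counts, brute)

    def test_removal_rate_is_binomial(self, params):
        """1000 overcrowded-cell checks at p = 1% remove 10 +- 3*sqrt(9.9)."""
        p = params.replace(apoptosis_probability=0.01)
        rng = np.random.default_rng(7)
        removed = 0
        checks = 0
        trial = 0
        while checks < 1000:
            # dense LEP cluster: everyone overcrowded
            st = CpmState(60, 60)
            ids = []
            for i in range(16):
                idx = st.new_cell(LEP, p)
                y, x = 20 + 5 * (i // 4), 20 + 5 * (i % 4)
                st.sites[y:y + 4, x:x + 4] = idx
                ids.append(idx)
            st.refresh()
            lep, counts = crowding_counts(st, p)
            n_over = int((counts >= p.overcrowding_threshold).sum())
            assert n_over == 16
            removed += len(apoptosis_check(st, p, rng))
            checks += n_over
            trial += 1
        mean, sd = checks * 0.01, math.sqrt(checks * 0.01 * 0.99)
        assert abs(removed - mean) <= 3 * sd

    def test_removal_clears_pixels_and_links(self, params):
        p = params.replace(apoptosis_probability=1.0)
        # probability is validated <= 1%; bypass validation, this is a unit test
        st = CpmState(60, 60)
        ids = []
        for i in range(12):
            idx = st.new_cell(LEP, p)
            y, x = 20 + 5 * (i // 4), 20 + 5 * (i % 4)
            st.sites[y:y + 4, x:x + 4] = idx
            ids.append(idx)
        st.refresh()
        from ductsim import rebuild_links
        rebuild_links(st, p)
        gone = apoptosis_check(st, p, np.random.default_rng(1))
        assert set(gone) == set(ids)
        assert not (st.sites > 0).any()
        assert (st.link_partner[ids] == -1).all()


class TestNecrosis:
    def _mep_wall_state(self, params, lep_x):
        st = CpmState(160, 40)
        mep = st.new_cell(MEP, params)
        st.sites[5:35, 3:13] = mep          # MEP wall: pixels up to x = 12
        lep = st.new_cell(LEP, params)
        st.sites[16:24, lep_x:lep_x + 8] = lep
        st.refresh()
        return st, lep

    def test_boundary_is_inclusive_at_100px(self, params):
        # LEP center of mass exactly 100 px from the nearest MEP pixel
        st, lep = self._mep_wall_state(params, lep_x=109)  # com x = 112.5
        st.sum_x[lep] = 112.0 * st.vol[lep]  # pin the COM to exactly 112 -> d = 100
        newly = necrosis_check(st, params)
        assert newly == [lep]
        assert st.typ[lep] == NECROTIC

    def test_within_99px_no_change(self, params):
        st, lep = self._mep_wall_state(params, lep_x=100)  # com x = 103.5, d = 91.5
        assert necrosis_check(st, params) == []
        assert st.typ[lep] == LEP

    def test_distances_match_exhaustive_search(self, params):
        """COM-to-nearest-MEP-pixel distances agree with a brute-force scan
        over every MEP pixel on a small fixture."""
        rng = np.random.default_rng(8)
        st = CpmState(50, 50)
        mep_ids = []
        for k in range(2):
            idx = st.new_cell(MEP, params)
            y, x = rng.integers(4, 40, 2)
            st.sites[y:y + 5, x:x + 5] = idx
            mep_ids.append(idx)
        lep_ids = []
        for k in range(3):
            idx = st.new_cell(LEP, params)
            y, x = rng.integers(4, 40, 2)
            mask = st.sites[y:y + 4, x:x + 4] == 0
            st.sites[y:y + 4, x:x + 4][mask] = idx
            lep_ids.append(idx)
        st.refresh()
        from scipy import ndimage
        mep_mask = st.typ[st.sites] == MEP
        ys, xs = np.nonzero(mep_mask)
        for lep in lep_ids:
            if st.vol[lep] == 0:
                continue
            cx, cy = st.com(lep)
            brute = np.min(np.hypot(xs - cx, ys - cy))
            dist = ndimage.distance_transform_edt(~mep_mask)
            iy, ix = int(round(cy)), int(round(cx))
            assert dist[iy, ix] == pytest.approx(
                np.min(np.hypot(xs - ix, ys - iy)))
            assert abs(brute - dist[iy, ix]) <= 1.5  # COM rounding to pixel

    def test_no_mep_skips_rule(self, params, caplog):
        st = CpmState(30, 30)
        lep = st.new_cell(LEP, params)
        st.sites[5:15, 5:15] = lep
        st.refresh()
        with caplog.at_level("WARNING"):
            assert necrosis_check(st, params) == []
        assert "no MEP" in caplog.text

    def test_necrotic_cells_never_selected_for_mitosis(self, ring, params):
        state, geom = ring
        victims = state.live_indices(types=LEP)[:10]
        state.typ[victims] = NECROTIC
        rng = np.random.default_rng(9)
        for _ in range(50):
            chosen = select_mitotic_cells(state, params, geom, rng)
            assert not set(chosen.tolist()) & set(victims.tolist())
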