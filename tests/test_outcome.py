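"""Bridging path search (vs. BFS oracle), outcome classification, mRUST
scoring, virtual radiographs."""

from collections import deque

import numpy as np
import pytest

from callusim.grid import Quadrant, Region, initial_state
from callusim.outcome import (bridging_dates, classify_outcome,
                              project_radiograph, quadrant_bridged,
                              score_mrust)

from conftest import fully_lamellar


def _bfs_spans(mask):
    """Exhaustive 6-connected breadth-first search: does any component of
    ``mask`` touch both the first and last z-slice?  Independent oracle."""
    nx, ny, nz = mask.shape
    starts = [(i, j, 0) for i in range(nx) for j in range(ny) if mask[i, j, 0]]
    seen = set(starts)
    queue = deque(starts)
    while queue:
        i, j, k = queue.popleft()
        if k == nz - 1:
            return True
        for di, dj, dk in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0),
                           (0, 0, 1), (0, 0, -1)):
            ni, nj, nk = i + di, j + dj, k + dk
            if (0 <= ni < nx and 0 <= nj < ny and 0 <= nk < nz
                    and mask[ni, nj, nk] and (ni, nj, nk) not in seen):
                seen.add((ni, nj, nk))
                queue.append((ni, nj, nk))
    return False


def _path_mask(domain, state, qcode, threshold):
    zlo, zhi = domain.healing_z_slices()
    allowed = np.isin(domain.region, (Region.CORTEX, Region.GAP, Region.ENVELOPE))
    return ((state.lamellar >= threshold) & allowed
            & (domain.quadrant == qcode))[:, :, zlo:zhi + 1]


class TestQuadrantBridged:
    def test_solid_lamellar_column_bridges(self, favorable_domain):
        state = fully_lamellar(favorable_domain)
        for q in ("anterior", "posterior", "medial", "lateral"):
            assert quadrant_bridged(state, favorable_domain, q)

    def test_day0_not_bridged(self, favorable_domain, favorable_state):
        for q in ("anterior", "posterior", "medial", "lateral"):
            assert not quadrant_bridged(favorable_state, favorable_domain, q)

    def test_flips_exactly_at_70_percent(self, favorable_domain):
        """Uniform lamellar 0.69 in the healing region does not bridge;
        0.70 does (the rubric's >= 70% criterion is inclusive)."""
        for value, expected in ((0.69, False), (0.70, True)):
            state = initial_state(favorable_domain)
            heal = favorable_domain.healing_mask
            state.lamellar[heal] = value
            state.connective[heal] = 1 - value
            assert quadrant_bridged(state, favorable_domain, "anterior") is expected

    def test_subthreshold_band_breaks_path(self, favorable_domain):
        """Dropping one transverse healing-region band inside a quadrant's
        sector below threshold removes its spanning path (verified against
        the BFS oracle); other quadrants keep theirs."""
        state = fully_lamellar(favorable_domain)
        gap = favorable_domain.region == Region.GAP
        ks = np.nonzero(gap.any(axis=(0, 1)))[0]  # slab z-layers
        band = np.zeros_like(gap)
        band[:, :, ks] = True
        band &= favorable_domain.healing_mask
        in_q = favorable_domain.quadrant == Quadrant.ANTERIOR
        state.lamellar[band & in_q] = 0.5
        state.connective[band & in_q] = 0.5
        assert not quadrant_bridged(state, favorable_domain, "anterior")
        assert not _bfs_spans(_path_mask(favorable_domain, state,
                                         Quadrant.ANTERIOR, 0.7))
        assert quadrant_bridged(state, favorable_domain, "medial")

    def test_matches_bfs_oracle_on_random_fields(self, favorable_domain, rng):
        """Randomized lamellar fields: the detector agrees with an
        exhaustive BFS on every trial."""
        state = initial_state(favorable_domain)
        heal = favorable_domain.healing_mask
        mismatch = 0
        for _ in range(300):
            lam = np.zeros(state.shape)
            lam[heal] = rng.random(heal.sum()) < 0.45
            state.lamellar = np.where(heal, lam, state.lamellar)
            got = quadrant_bridged(state, favorable_domain, "lateral")
            want = _bfs_spans(_path_mask(favorable_domain, state,
                                         Quadrant.LATERAL, 0.7))
            mismatch += got is not want
        assert mismatch == 0

    def test_threshold_monotonicity(self, favorable_domain, rng):
        """Raising the lamellar threshold never turns non-bridged into
        bridged."""
        state = initial_state(favorable_domain)
        heal = favorable_domain.healing_mask
        state.lamellar[heal] = rng.random(heal.sum())
        results = [quadrant_bridged(state, favorable_domain, "posterior",
                                    threshold=t)
                   for t in (0.3, 0.5, 0.7, 0.9)]
        assert sorted(results, reverse=True) == results

    def test_diagonal_chain_needs_26_connectivity(self, favorable_domain):
        """A corner-touching lamellar chain across the gap bridges under
        26-connectivity but not under the default face connectivity."""
        state = fully_lamellar(favorable_domain)
        gap = favorable_domain.region == Region.GAP
        ks = np.nonzero(gap.any(axis=(0, 1)))[0]
        band = np.zeros_like(gap)
        band[:, :, ks] = True
        band &= favorable_domain.healing_mask
        in_q = favorable_domain.quadrant == Quadrant.ANTERIOR
        state.lamellar[band & in_q] = 0.0
        state.connective[band & in_q] = 1.0
        # rebuild a diagonal staircase through the slab: one voxel per layer,
        # offset by one in x between consecutive layers (corner contact only)
        sel = band & in_q
        start = next((i, j)
                     for i, j in zip(*np.nonzero(sel[:, :, ks[0]]))
                     if all(sel[i + s, j, k] for s, k in enumerate(ks)))
        for step, k in enumerate(ks):
            state.lamellar[start[0] + step, start[1], k] = 1.0
            state.connective[start[0] + step, start[1], k] = 0.0
        assert not quadrant_bridged(state, favorable_domain, "anterior",
                                    connectivity=6)
        assert quadrant_bridged(state, favorable_domain, "anterior",
                                connectivity=26)

    def test_unknown_quadrant_rejected(self, favorable_domain, favorable_state):
        with pytest.raises(ValueError, match="unknown quadrant"):
            quadrant_bridged(favorable_state, favorable_domain, "superior")


class TestBridgingDates:
    def test_first_occurrence_from_snapshots(self, favorable_domain):
        """Detector output equals a linear re-scan of the snapshots."""
        day0 = initial_state(favorable_domain)
        healed = fully_lamellar(favorable_domain)
        snaps = [(0, day0), (100, day0), (150, healed), (200, healed)]
        dates = bridging_dates(snaps, favorable_domain)
        # oracle: explicit linear scan
        expected = {}
        for name, code in (("anterior", Quadrant.ANTERIOR),
                           ("posterior", Quadrant.POSTERIOR),
                           ("medial", Quadrant.MEDIAL),
                           ("lateral", Quadrant.LATERAL)):
            expected[name] = None
            for day, st in snaps:
                if quadrant_bridged(st, favorable_domain, code):
                    expected[name] = day
                    break
        assert dates == expected
        assert all(d == 150 for d in dates.values())

    def test_never_bridged_is_none(self, favorable_domain):
        day0 = initial_state(favorable_domain)
        dates = bridging_dates([(0, day0), (280, day0)], favorable_domain)
        assert all(d is None for d in dates.values())


class TestClassifyOutcome:
    def test_union_with_third_smallest_date(self):
        dates = {"anterior": 120, "posterior": 150, "medial": 180,
                 "lateral": None}
        rep = classify_outcome(dates)
        assert rep.outcome == "union"
        assert rep.consolidation_day == 180

    def test_two_bridged_is_non_union(self):
        dates = {"anterior": 100, "posterior": 200, "medial": None,
                 "lateral": None}
        rep = classify_outcome(dates)
        assert rep.outcome == "non_union"
        assert rep.consolidation_day is None

    def test_window_boundary_inclusive(self):
        dates = {q: 279 for q in ("anterior", "posterior", "medial", "lateral")}
        assert classify_outcome(dates).outcome == "union"
        dates280 = {q: 280 for q in dates}
        assert classify_outcome(dates280).outcome == "union"
        dates281 = {q: 281 for q in dates}
        assert classify_outcome(dates281).outcome == "non_union"

    def test_min_quadrants_flip(self):
        dates = {"anterior": 50, "posterior": 60, "medial": None,
                 "lateral": None}
        assert classify_outcome(dates, min_quadrants=2).outcome == "union"
        assert classify_outcome(dates, min_quadrants=3).outcome == "non_union"


class TestMRUST:
    def test_day0_minimum_score(self, favorable_domain, favorable_state):
        m = score_mrust(favorable_state, favorable_domain)
        assert m.total == 4
        assert all(s == 1 for s in m.cortex_scores.values())
        assert not m.consolidated

    def test_fully_remodeled_maximum_score(self, favorable_domain):
        m = score_mrust(fully_lamellar(favorable_domain), favorable_domain)
        assert m.total == 16
        assert all(s == 4 for s in m.cortex_scores.values())
        assert m.consolidated

    def test_three_threes_and_a_one_consolidated(self, favorable_domain):
        """Bridged-with-line callus on three cortices, nothing on the
        fourth: total 10, consolidated."""
        state = fully_lamellar(favorable_domain)
        gap = favorable_domain.region == Region.GAP
        env = favorable_domain.region == Region.ENVELOPE
        # leave a lucent fracture line in the gap of three quadrants
        for q in (Quadrant.POSTERIOR, Quadrant.MEDIAL, Quadrant.LATERAL):
            sel = gap & (favorable_domain.quadrant == q)
            state.lamellar[sel] = 0.0
            state.connective[sel] = 1.0
        # strip the fourth quadrant bare
        sel = (gap | env) & (favorable_domain.quadrant == Quadrant.ANTERIOR)
        state.lamellar[sel] = 0.0
        state.connective[sel] = 1.0
        m = score_mrust(state, favorable_domain)
        assert m.cortex_scores["anterior"] == 1
        assert m.cortex_scores["posterior"] == 3
        assert m.cortex_scores["medial"] == 3
        assert m.cortex_scores["lateral"] == 3
        assert m.total == 10
        assert m.consolidated

    def test_four_twos_not_consolidated(self, favorable_domain):
        """Non-bridging callus on all four cortices: total 8, below the
        consolidation cut of 9."""
        state = initial_state(favorable_domain)
        env = favorable_domain.region == Region.ENVELOPE
        zlo, zhi = favorable_domain.healing_z_slices()
        mid = (zlo + zhi) // 2
        patch = env.copy()
        patch[:, :, :mid] = False  # callus only in the upper half: no span
        state.woven[patch] = 0.3
        state.connective[patch] = 0.7
        m = score_mrust(state, favorable_domain)
        assert all(s == 2 for s in m.cortex_scores.values())
        assert m.total == 8
        assert not m.consolidated


class TestRadiograph:
    def test_cortex_walls_visible_in_empty_region(self, favorable_domain,
                                                  favorable_state):
        """With no callus the AP projection shows the two cortical walls
        as bright bands flanking a dimmer center."""
        radiograph = project_radiograph(favorable_state, favorable_domain,
                                        "AP", nail_density=0.0)
        img = radiograph.image  # (ny, nz)
        profile = img[:, 2]  # distal slice away from the gap
        _, y, _ = favorable_domain.coords()
        wall = (np.abs(y) > 6.0) & (np.abs(y) < 13.0)
        center = np.abs(y) < 3.0
        # tangential chords through the cortical ring are longer than the
        # two straight wall crossings at the center
        assert profile[wall].max() > 1.2 * profile[center].mean()

    def test_linearity_in_woven_density(self, favorable_domain):
        base = initial_state(favorable_domain)
        heal = favorable_domain.healing_mask
        imgs = {}
        for c in (0.2, 0.4):
            state = initial_state(favorable_domain)
            state.woven[heal] = c
            state.connective[heal] = 1 - c
            imgs[c] = project_radiograph(state, favorable_domain, "lateral").image
        base_img = project_radiograph(base, favorable_domain, "lateral").image
        assert np.allclose(imgs[0.4] - base_img, 2 * (imgs[0.2] - base_img),
                           atol=1e-12)

    def test_projection_conserves_density(self, favorable_domain):
        """Sum of the image equals voxel-sum of density times path length
        (discrete Fubini)."""
        state = fully_lamellar(favorable_domain)
        radiograph = project_radiograph(state, favorable_domain, "AP",
                                        w_woven=0.5, w_lamellar=1.0,
                                        nail_density=3.0)
        density = 0.5 * state.woven + 1.0 * state.lamellar
        density[favorable_domain.region == Region.NAIL] = 3.0
        expected = density.sum() * favorable_domain.voxel_size
        assert radiograph.image.sum() == pytest.approx(expected)

    def test_unknown_view_rejected(self, favorable_domain, favorable_state):
        with pytest.raises(ValueError, match="view"):
            project_radiograph(favorable_state, favorable_domain, "oblique")
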