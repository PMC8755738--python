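"""ROIs, regional metrics, vessel stratification, skewness."""

import numpy as np
import pytest

from ulmkit import (Track, TrackSet, ULMImage, blood_volume, intervessel_distance,
                    kmeans_vessel_split, mask_roi, region_velocity_and_soam,
                    roi_from_vertices, vascularity, velocity_skewness)

PITCH = 4.928


def make_image(density):
    density = np.asarray(density)
    return ULMImage(density=density.astype(np.int64),
                    speed_sum=np.zeros(density.shape),
                    direction_sum=np.zeros(density.shape), pitch_um=PITCH)


def track_at(tid, points, frame0=0):
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    return Track(tid, frame0 + np.arange(len(pts)), pts)


class TestROI:
    GRID = (400, 400)  # ~2 x 2 mm super-resolved

    def test_square_area_with_high_tension(self):
        # 1 mm x 1 mm axis-aligned square; high tension bounds the bulge
        v = np.array([(500.0, 500.0), (500.0, 1500.0), (1500.0, 1500.0),
                      (1500.0, 500.0)])
        roi = roi_from_vertices(v, self.GRID, PITCH, tension=40.0)
        area_mm2 = roi.mask.sum() * (PITCH / 1000.0) ** 2
        assert area_mm2 == pytest.approx(1.0, rel=0.02)

    def test_collinear_vertices_rejected(self):
        v = np.array([(100.0, 100.0), (100.0, 500.0), (100.0, 900.0)])
        with pytest.raises(ValueError, match="degenerate"):
            roi_from_vertices(v, self.GRID, PITCH)

    def test_self_intersecting_boundary_names_segments(self):
        # bow-tie ordering of four corners (asymmetric so the ring has area)
        v = np.array([(500.0, 500.0), (1500.0, 1500.0), (500.0, 1500.0),
                      (1200.0, 500.0)])
        with pytest.raises(ValueError, match="segments"):
            roi_from_vertices(v, self.GRID, PITCH, tension=10.0)

    def test_pentagon_boundary_passes_through_vertices(self):
        ang = np.radians(90 + np.arange(5) * 72)
        v = 1000.0 + 400.0 * np.column_stack([np.cos(ang), np.sin(ang)])
        roi = roi_from_vertices(v, self.GRID, PITCH)
        for vert in v:
            d = np.min(np.hypot(*(roi.boundary - vert).T))
            assert d <= PITCH / 2


class TestBloodVolume:
    def _roi(self):
        mask = np.zeros((100, 100), dtype=bool)
        mask[40:60, 40:60] = True
        return mask_roi(mask, "box", PITCH)

    def test_mean_over_acquisitions(self):
        roi = self._roi()
        inside = (250.0, 250.0)

        def acq(n, base):
            return TrackSet(tracks=[track_at(base + i, [inside, inside]) for i in
                                    range(n)])

        assert blood_volume([acq(10, 0), acq(20, 100)], roi) == 15.0

    def test_disjoint_tracks_count_zero(self):
        roi = self._roi()
        ts = TrackSet(tracks=[track_at(0, [(10.0, 10.0), (12.0, 10.0)])])
        assert blood_volume([ts], roi) == 0.0

    def test_boundary_crossings_counted_once(self):
        roi = self._roi()
        # weave in and out of the ROI three times
        pts = [(250.0, 250.0), (10.0, 250.0), (250.0, 250.0), (10.0, 250.0),
               (250.0, 250.0)]
        ts = TrackSet(tracks=[track_at(0, pts)])
        assert blood_volume([ts], roi) == 1.0

    def test_invariant_to_splitting_and_ordering(self):
        roi = self._roi()
        rng = np.random.default_rng(0)
        tracks = [track_at(i, rng.uniform(0, 490, (4, 2))) for i in range(30)]
        whole = TrackSet(tracks=tracks)
        split = [TrackSet(tracks=tracks[:13]), TrackSet(tracks=tracks[13:])]
        merged = TrackSet(tracks=tracks[::-1])
        n_whole = blood_volume([whole], roi)
        assert blood_volume([merged], roi) == n_whole
        assert (len([t for ts in split for t in ts.tracks])
                == len(whole.tracks))
        counts = [blood_volume([s], roi) for s in split]
        assert sum(counts) == n_whole

    def test_zero_acquisitions_rejected(self):
        with pytest.raises(ValueError):
            blood_volume([], self._roi())


class TestVascularity:
    def test_full_and_empty(self):
        mask = np.ones((20, 20), dtype=bool)
        roi = mask_roi(mask, "all", PITCH)
        assert vascularity(make_image(np.ones((20, 20))), roi) == 100.0
        assert vascularity(make_image(np.zeros((20, 20))), roi) == 0.0

    def test_vessel_band_counting_oracle(self):
        density = np.zeros((50, 50))
        density[20:22, :] = 3  # 2-pixel-wide straight vessel
        roi_mask = np.zeros((50, 50), dtype=bool)
        roi_mask[10:40, 10:40] = True
        roi = mask_roi(roi_mask, "box", PITCH)
        expected = 100.0 * (2 * 30) / (30 * 30)
        assert vascularity(make_image(density), roi) == pytest.approx(expected)

    def test_union_is_area_weighted_mean_of_disjoint_parts(self):
        rng = np.random.default_rng(1)
        density = (rng.random((40, 40)) < 0.3).astype(float)
        a = np.zeros((40, 40), dtype=bool)
        b = np.zeros((40, 40), dtype=bool)
        a[:, :10] = True
        b[:, 25:] = True
        img = make_image(density)
        va = vascularity(img, mask_roi(a, "a", PITCH))
        vb = vascularity(img, mask_roi(b, "b", PITCH))
        vu = vascularity(img, mask_roi(a | b, "ab", PITCH))
        expected = (va * a.sum() + vb * b.sum()) / (a.sum() + b.sum())
        assert vu == pytest.approx(expected, abs=1e-12)
        assert min(va, vb) <= vu <= max(va, vb)


class TestRegionVelocityAndSOAM:
    def test_track_weighted_means(self):
        roi = mask_roi(np.ones((100, 100), dtype=bool), "all", PITCH)
        t1 = track_at(0, [(50.0, 50.0 + 2.0 * i) for i in range(10)])  # 2 mm/s
        t2 = track_at(1, [(150.0, 50.0 + 6.0 * i) for i in range(10)])  # 6 mm/s
        speed, soam = region_velocity_and_soam(TrackSet(tracks=[t1, t2]), roi)
        assert speed == pytest.approx(4.0, rel=1e-9)
        assert soam == pytest.approx(0.0, abs=1e-9)

    def test_no_intersection_flagged(self):
        mask = np.zeros((100, 100), dtype=bool)
        mask[90:, 90:] = True
        roi = mask_roi(mask, "corner", PITCH)
        ts = TrackSet(tracks=[track_at(0, [(5.0, 5.0), (6.0, 5.0)])])
        with pytest.raises(ValueError, match="no tracks intersect"):
            region_velocity_and_soam(ts, roi)


class TestKMeansSplit:
    def test_bimodal_density_separates(self):
        rng = np.random.default_rng(2)
        density = np.zeros((30, 30))
        low = rng.random((30, 30)) < 0.3
        density[low] = 10
        density[5:8, 5:25] = 1000
        seg = kmeans_vessel_split(density, k=2, n_large=1)
        np.testing.assert_array_equal(seg.large_mask, density == 1000)
        np.testing.assert_array_equal(seg.small_mask, density == 10)

    def test_order_invariance(self):
        rng = np.random.default_rng(3)
        density = rng.integers(0, 50, (40, 40))
        seg1 = kmeans_vessel_split(density, k=6)
        perm = rng.permutation(40)
        seg2 = kmeans_vessel_split(density[perm][:, perm], k=6)
        np.testing.assert_array_equal(seg1.labels[perm][:, perm], seg2.labels)

    def test_six_exact_levels_match_nearest_centroid_oracle(self):
        levels = np.array([1, 4, 16, 64, 256, 1024], dtype=float)
        rng = np.random.default_rng(4)
        density = levels[rng.integers(0, 6, (30, 30))]
        density[rng.random((30, 30)) < 0.2] = 0
        if len(np.unique(density[density > 0])) < 6:  # keep all levels present
            density[:6, 0] = levels
        seg = kmeans_vessel_split(density, k=6)
        # each level its own cluster, ranked ascending
        for rank, lv in enumerate(levels):
            assert set(np.unique(seg.labels[density == lv])) == {rank}
        # oracle: nearest centroid in log10 space
        centroids = seg.centroids
        logd = np.log10(density[density > 0])
        oracle = np.argmin(np.abs(logd[:, None] - centroids[None, :]), axis=1)
        np.testing.assert_array_equal(oracle, seg.labels[density > 0])

    def test_too_few_levels_rejected(self):
        density = np.zeros((10, 10))
        density[:2] = 5
        with pytest.raises(ValueError, match="smaller k"):
            kmeans_vessel_split(density, k=6)


class TestIntervesselDistance:
    def test_parallel_vessels_analytic(self):
        # two 1-px vessels 100 µm apart; ROI strictly between them
        sep_px = int(round(100.0 / PITCH))  # ~20 px
        large = np.zeros((60, 40), dtype=bool)
        large[10, :] = True
        large[10 + sep_px, :] = True
        roi_mask = np.zeros((60, 40), dtype=bool)
        roi_mask[11:10 + sep_px, :] = True
        roi = mask_roi(roi_mask, "between", PITCH)
        metric = intervessel_distance(large, roi)
        # oracle: mean of min(d, L-d) for uniform d over the strip
        rows = np.arange(11, 10 + sep_px)
        d = np.minimum(rows - 10, 10 + sep_px - rows) * PITCH
        assert metric == pytest.approx(2 * d.mean(), rel=0.02)
        assert metric == pytest.approx(50.0, rel=0.1)

    def test_fully_covered_roi_zero(self):
        large = np.ones((20, 20), dtype=bool)
        roi = mask_roi(np.ones((20, 20), dtype=bool), "all", PITCH)
        assert intervessel_distance(large, roi) == 0.0

    def test_widening_roi_increases_metric(self):
        large = np.zeros((80, 40), dtype=bool)
        large[10, :] = True
        narrow = np.zeros((80, 40), dtype=bool)
        narrow[11:30, :] = True
        wide = np.zeros((80, 40), dtype=bool)
        wide[11:60, :] = True
        m1 = intervessel_distance(large, mask_roi(narrow, "n", PITCH))
        m2 = intervessel_distance(large, mask_roi(wide, "w", PITCH))
        assert m2 > m1

    def test_empty_mask_rejected(self):
        roi = mask_roi(np.ones((10, 10), dtype=bool), "all", PITCH)
        with pytest.raises(ValueError):
            intervessel_distance(np.zeros((10, 10), dtype=bool), roi)


class TestVelocitySkewness:
    def test_symmetric_sample_zero(self):
        assert velocity_skewness(np.array([1.0, 2.0, 3.0])) == pytest.approx(0.0,
                                                                             abs=1e-12)

    def test_right_tail_positive(self):
        assert velocity_skewness(np.array([1.0, 1.0, 1.0, 10.0])) > 0

    def test_lognormal_matches_closed_form(self):
        sigma = 0.5
        rng = np.random.default_rng(5)
        draws = rng.lognormal(mean=0.0, sigma=sigma, size=100_000)
        g1 = velocity_skewness(draws)
        es2 = np.exp(sigma ** 2)
        expected = (es2 + 2) * np.sqrt(es2 - 1)
        assert g1 == pytest.approx(expected, rel=0.05)

    def test_location_scale_invariance(self):
        rng = np.random.default_rng(6)
        x = rng.gamma(2.0, size=500)
        base = velocity_skewness(x)
        assert velocity_skewness(3.5 * x + 11.0) == pytest.approx(base, abs=1e-9)

    def test_zero_variance_flagged(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            assert np.isnan(velocity_skewness(np.array([2.0, 2.0, 2.0])))

    def test_too_few_tracks_rejected(self):
        with pytest.raises(ValueError):
            velocity_skewness(np.array([1.0, 2.0]))
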