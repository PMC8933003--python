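"""Nearest-neighbor, overlap, randomization-null and pixel colocalization statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import polycolo as pc
from polycolo.clustering import CLUSTER_COLUMNS


def make_map(centroids, radii, roi=(0.0, 0.0, 10000.0, 10000.0), pixel_nm=10.0, channel="ch"):
    """ClusterMap from explicit centroids/radii, with disk-rasterized footprints."""
    centroids = np.asarray(centroids, dtype=float).reshape(-1, 2)
    radii = np.broadcast_to(np.asarray(radii, dtype=float), (len(centroids),))
    rows, fps = [], []
    x0, y0, x1, y1 = roi
    ny = int(np.ceil((y1 - y0) / pixel_nm))
    nx = int(np.ceil((x1 - x0) / pixel_nm))
    for k, ((cx, cy), r) in enumerate(zip(centroids, radii)):
        area = np.pi * r**2
        rows.append(
            {
                "id": k, "x_nm": cx, "y_nm": cy, "area_nm2": area, "area_raw_nm2": area,
                "footprint_area_nm2": area, "n_locs": 10, "radius_nm": r,
            }
        )
        rr, cc = np.mgrid[0:ny, 0:nx]
        px = (cc + 0.5) * pixel_nm + x0
        py = (rr + 0.5) * pixel_nm + y0
        inside = (px - cx) ** 2 + (py - cy) ** 2 <= max(r, pixel_nm / 2) ** 2
        fps.append(np.argwhere(inside))
    return pc.ClusterMap(
        pixel_nm=pixel_nm, roi=roi, channel=channel,
        clusters=pd.DataFrame(rows, columns=CLUSTER_COLUMNS), footprints=fps,
    )


class TestNearestNeighbor:
    def test_coincident_clusters_distance_zero(self):
        a = make_map([(500.0, 500.0)], 50.0)
        b = make_map([(500.0, 500.0)], 30.0)
        res = pc.nearest_neighbor_distances(a, b)
        assert res.distances_nm[0] == 0.0

    def test_three_four_five_triangle(self):
        a = make_map([(0.0, 0.0)], 10.0, roi=(-100, -100, 1000, 1000))
        b = make_map([(300.0, 400.0)], 10.0, roi=(-100, -100, 1000, 1000))
        res = pc.nearest_neighbor_distances(a, b)
        assert res.mean_nm == pytest.approx(500.0)

    def test_matches_brute_force_all_pairs_minimum(self, rng):
        for _ in range(20):
            na, nb = rng.integers(2, 50, size=2)
            ca = rng.uniform(0, 5000, size=(na, 2))
            cb = rng.uniform(0, 5000, size=(nb, 2))
            a = make_map(ca, 20.0, roi=(0, 0, 5000, 5000))
            b = make_map(cb, 20.0, roi=(0, 0, 5000, 5000))
            res = pc.nearest_neighbor_distances(a, b)
            brute = np.sqrt(((ca[:, None, :] - cb[None, :, :]) ** 2).sum(-1)).min(axis=1)
            np.testing.assert_allclose(res.distances_nm, brute, rtol=1e-12)

    def test_empty_b_channel_rejected(self):
        a = make_map([(1.0, 1.0)], 10.0)
        b = make_map(np.empty((0, 2)), [])
        with pytest.raises(ValueError):
            pc.nearest_neighbor_distances(a, b)


class TestOverlapFraction:
    @pytest.mark.parametrize("criterion", ["disk", "pixel"])
    def test_identical_maps_fully_overlap(self, criterion):
        m = make_map([(500.0, 500.0), (2000.0, 2000.0)], 100.0, roi=(0, 0, 3000, 3000))
        res = pc.overlap_fraction(m, m, criterion=criterion)
        assert res.fraction_ab == 1.0 and res.fraction_ba == 1.0

    @pytest.mark.parametrize("criterion", ["disk", "pixel"])
    def test_disjoint_halves_do_not_overlap(self, criterion):
        a = make_map([(1000.0, 1000.0)], 100.0, roi=(0, 0, 8000, 8000))
        b = make_map([(7000.0, 7000.0)], 100.0, roi=(0, 0, 8000, 8000))
        res = pc.overlap_fraction(a, b, criterion=criterion)
        assert res.fraction_ab == 0.0 and res.fraction_ba == 0.0

    def test_mismatched_grids_rejected_in_pixel_mode(self):
        a = make_map([(100.0, 100.0)], 50.0, pixel_nm=10.0)
        b = make_map([(100.0, 100.0)], 50.0, pixel_nm=20.0)
        with pytest.raises(ValueError):
            pc.overlap_fraction(a, b, criterion="pixel")

    def test_colocalized_synthetic_fraction_tracks_ground_truth(self):
        # coloc_fraction 0.27, no background: B->A overlap within 3 binomial sd
        fracs, truths, ns = [], [], []
        for seed in range(4):
            cfg = pc.SimulationConfig(seed=seed + 40, background_density=0.0)
            t1, t2, truth = pc.simulate_localizations(cfg)
            roi = (0, 0, cfg.roi_width_nm, cfg.roi_height_nm)
            m1 = pc.segment_clusters(t1, roi=roi)
            m2 = pc.segment_clusters(t2, roi=roi)
            fracs.append(pc.overlap_fraction(m1, m2).fraction_ba * len(m2))
            truths.append(truth.realized_coloc_fraction * len(truth.channel("ch2")))
            ns.append(len(m2))
        n = sum(ns)
        p = sum(truths) / n
        assert abs(sum(fracs) / n - p) <= 3.0 * np.sqrt(p * (1 - p) / n) + 0.02


class TestCostesRandomize:
    def test_tiny_clusters_rarely_overlap_by_chance(self):
        # each disk covers 0.01% of the ROI: null overlap far below 1%
        a = make_map([(5000.0, 5000.0)], 56.0)  # pi*56^2 / 1e8 ~ 1e-4
        b = make_map([(5000.0, 5000.0)], 56.0)
        res = pc.costes_randomize(a, b, n_iter=400, seed=1)
        assert res.null_mean < 0.01

    def test_fully_colocalized_data_highly_significant(self):
        rng = np.random.default_rng(2)
        cents = rng.uniform(1000, 9000, size=(40, 2))
        a = make_map(cents, 60.0)
        b = make_map(cents, 40.0)
        res = pc.costes_randomize(a, b, n_iter=199, seed=3)
        assert res.observed == 1.0
        assert res.null_mean < 0.2
        assert res.p_value <= 1.0 / 200.0

    def test_randomization_preserves_count_and_area(self):
        from polycolo.colocalization import _randomize_map

        m = make_map([(500.0, 500.0), (2000.0, 1500.0)], [80.0, 120.0], roi=(0, 0, 4000, 4000))
        rng = np.random.default_rng(0)
        for criterion in ("disk", "pixel"):
            shuffled = _randomize_map(m, rng, criterion)
            assert len(shuffled) == len(m)
            np.testing.assert_allclose(np.sort(shuffled.radii), np.sort(m.radii))
            assert sum(len(fp) for fp in shuffled.footprints) == sum(
                len(fp) for fp in m.footprints
            )

    def test_cluster_larger_than_roi_rejected(self):
        m = make_map([(500.0, 500.0)], 600.0, roi=(0, 0, 1000, 1000))
        with pytest.raises(ValueError):
            pc.costes_randomize(m, m, n_iter=100, seed=0)

    def test_too_few_iterations_rejected(self):
        m = make_map([(500.0, 500.0)], 50.0)
        with pytest.raises(ValueError):
            pc.costes_randomize(m, m, n_iter=50, seed=0)

    def test_randomization_stretches_nearest_neighbor_distances(self):
        from polycolo.colocalization import _randomize_map

        wins = 0
        for seed in range(5):
            cfg = pc.SimulationConfig(seed=seed + 60, roi_width_nm=7000, roi_height_nm=7000)
            t1, t2, _ = pc.simulate_localizations(cfg)
            roi = (0, 0, 7000, 7000)
            m1 = pc.segment_clusters(t1, roi=roi)
            m2 = pc.segment_clusters(t2, roi=roi)
            nn_obs = pc.nearest_neighbor_distances(m1, m2).mean_nm
            rng = np.random.default_rng(seed)
            nn_rand = pc.nearest_neighbor_distances(m1, _randomize_map(m2, rng, "disk")).mean_nm
            wins += nn_rand >= nn_obs
        assert wins >= 4


class TestPixelCoefficients:
    def test_pearson_self_correlation_is_one(self, rng):
        img = rng.random((16, 16))
        assert pc.pearson_coefficient(img, img) == pytest.approx(1.0)

    def test_pearson_anti_image_is_minus_one(self, rng):
        img = rng.random((16, 16))
        assert pc.pearson_coefficient(img, img.max() - img) == pytest.approx(-1.0)

    def test_pearson_affine_relation_is_one(self):
        img1 = np.arange(1.0, 10.0).reshape(3, 3)
        img2 = 2.0 * img1
        assert pc.pearson_coefficient(img1, img2) == pytest.approx(1.0)

    def test_pearson_zero_variance_flagged(self):
        with pytest.warns(UserWarning):
            r = pc.pearson_coefficient(np.ones((4, 4)), np.random.default_rng(0).random((4, 4)))
        assert np.isnan(r)

    @given(
        scale=st.floats(0.1, 50.0),
        offset=st.floats(-10.0, 10.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_pearson_invariant_under_positive_affine_transform(self, scale, offset):
        rng = np.random.default_rng(7)
        img1 = rng.random((8, 8))
        img2 = rng.random((8, 8))
        base = pc.pearson_coefficient(img1, img2)
        transformed = pc.pearson_coefficient(scale * img1 + offset, img2)
        assert transformed == pytest.approx(base, abs=1e-9)

    def test_manders_full_coverage_gives_one(self, rng):
        img1 = rng.random((8, 8)) + 1.0
        img2 = rng.random((8, 8)) + 1.0
        m1, m2 = pc.manders_coefficients(img1, img2, 0.0, 0.0)
        assert m1 == pytest.approx(1.0) and m2 == pytest.approx(1.0)

    def test_manders_disjoint_supports_give_zero(self):
        img1 = np.zeros((4, 4))
        img2 = np.zeros((4, 4))
        img1[:2] = 5.0
        img2[2:] = 5.0
        m1, m2 = pc.manders_coefficients(img1, img2)
        assert m1 == 0.0 and m2 == 0.0

    def test_manders_hand_computed_example(self):
        img1 = np.array([[1.0, 2.0], [3.0, 4.0]])
        img2 = np.array([[0.0, 5.0], [0.0, 6.0]])
        # above-zero img2 pixels hold intensities 2 and 4 of img1: M1 = 6/10
        # all img2 intensity sits where img1 > 0: M2 = 1
        m1, m2 = pc.manders_coefficients(img1, img2)
        assert m1 == pytest.approx(0.6)
        assert m2 == pytest.approx(1.0)

    def test_manders_all_zero_denominator_flagged(self):
        with pytest.warns(UserWarning):
            m1, m2 = pc.manders_coefficients(np.zeros((3, 3)), np.ones((3, 3)))
        assert np.isnan(m1)
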