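"""Property extraction: segmentation, geometry oracles, hashes."""

import math

import numpy as np
import pytest
from PIL import Image

from oracles import gift_wrap_hull_area
from numprops.features import (
    ArrayProperties,
    SegmentedArray,
    extract_dataset,
    feature_vector,
    geometry,
    hamming,
    hash_avg,
    hash_perceptual,
    hash_wavelet,
    segment,
    segment_colors,
    segment_panel,
)
from numprops.stimgen import PairSpec, build_pair, render


def seg_from_points(points):
    """SegmentedArray of single-pixel dots at the given (x, y) points."""
    pts = np.asarray(points, dtype=int)
    return SegmentedArray(centroids=pts.astype(float),
                          pixel_areas=np.ones(len(pts), dtype=int),
                          pixels=pts)


class TestGeometry:
    def test_perimeter_closed_form(self):
        # one disc of pixel area A has perim 2*sqrt(pi*A)
        seg = SegmentedArray(centroids=np.array([[10.0, 10.0]]),
                             pixel_areas=np.array([314]),
                             pixels=np.array([[10, 10]]))
        props = geometry(seg)
        assert props.perim_total == pytest.approx(2 * math.sqrt(math.pi * 314))

    def test_two_point_distances(self):
        props = geometry(seg_from_points([(0, 0), (3, 4)]))
        assert (props.dist_total, props.dist_mean, props.dist_sd) == (5, 5, 0)

    def test_collinear_hull_degenerate(self):
        props = geometry(seg_from_points([(0, 0), (3, 0), (6, 0)]))
        assert props.dist_total == 12
        assert props.dist_mean == 4
        assert props.convex_hull_area == 0.0

    def test_square_hull(self):
        props = geometry(seg_from_points([(0, 0), (10, 0), (0, 10),
                                          (10, 10)]))
        assert props.convex_hull_area == pytest.approx(100.0)

    def test_single_dot_distances_undefined(self):
        props = geometry(seg_from_points([(5, 5)]))
        assert np.isnan(props.dist_total)

    def test_hull_matches_gift_wrapping_oracle(self, rng):
        for _ in range(1000):
            n = rng.integers(3, 21)
            pts = rng.integers(0, 60, size=(n, 2))
            got = geometry(seg_from_points(pts)).convex_hull_area
            assert got == pytest.approx(gift_wrap_hull_area(pts), abs=1e-9)

    def test_distance_stats_match_quadratic_loop(self, rng):
        for _ in range(50):
            n = rng.integers(2, 15)
            pts = rng.uniform(0, 100, size=(n, 2))
            seg = SegmentedArray(centroids=pts,
                                 pixel_areas=np.ones(n, dtype=int),
                                 pixels=pts.astype(int))
            props = geometry(seg)
            dists = [math.dist(pts[i], pts[j])
                     for i in range(n) for j in range(i + 1, n)]
            assert props.dist_total == pytest.approx(sum(dists))
            assert props.dist_mean == pytest.approx(np.mean(dists))
            assert props.dist_sd == pytest.approx(np.std(dists))


def make_props(n_dots, scale=1.0):
    areas = scale * np.array([10.0, 20.0, 30.0])[:1] * n_dots
    return ArrayProperties(
        n_dots=n_dots, area_total=100 * scale, area_mean=10 * scale,
        area_sd=2 * scale, perim_total=60 * scale, perim_mean=6 * scale,
        perim_sd=1 * scale, convex_hull_area=500 * scale,
        ch_per_dot=50 * scale, ch_per_area=5 * scale, dist_total=300 * scale,
        dist_mean=30 * scale, dist_sd=4 * scale)


class TestFeatureVector:
    def test_identical_indices_give_unit_ratios(self):
        row = feature_vector(make_props(5), make_props(10))
        assert row["dot_ratio"] == 0.5
        for key in ("perim_total", "area_total", "convex_hull",
                    "dist_total"):
            assert row[key] == pytest.approx(1.0)

    def test_swap_invariance(self):
        a, b = make_props(5, scale=1.0), make_props(10, scale=2.0)
        r1 = feature_vector(a, b)
        r2 = feature_vector(b, a)
        assert r1 == r2

    def test_perimeter_ratio_equals_radius_sum_ratio(self, rng):
        # equivalent-circle identity: perim ratio == Σr_fewer / Σr_more
        areas_f = rng.uniform(50, 300, size=6)
        areas_m = rng.uniform(50, 300, size=9)

        def props(areas):
            r = np.sqrt(areas / np.pi)
            p = 2 * np.pi * r
            return ArrayProperties(
                n_dots=len(areas), area_total=areas.sum(),
                area_mean=areas.mean(), area_sd=areas.std(),
                perim_total=p.sum(), perim_mean=p.mean(), perim_sd=p.std(),
                convex_hull_area=1.0, ch_per_dot=1.0, ch_per_area=1.0,
                dist_total=1.0, dist_mean=1.0, dist_sd=1.0)

        row = feature_vector(props(areas_f), props(areas_m))
        rf = np.sqrt(areas_f / np.pi).sum()
        rm = np.sqrt(areas_m / np.pi).sum()
        assert row["perim_total"] == pytest.approx(rf / rm, rel=1e-12)

    def test_zero_denominator_flagged_missing(self):
        b = make_props(10)
        b.area_sd = 0.0
        row = feature_vector(make_props(5), b)
        assert np.isnan(row["area_sd"])

    def test_equal_counts_warns_and_uses_order(self):
        with pytest.warns(RuntimeWarning, match="equal dot counts"):
            row = feature_vector(make_props(5), make_props(5, scale=2.0))
        assert row["dot_ratio"] == 1.0
        assert row["area_total"] == pytest.approx(0.5)


class TestSegmentation:
    @staticmethod
    def disc_image(centers, radius=6, size=100):
        img = np.zeros((size, size), dtype=np.uint8)
        ys, xs = np.mgrid[0:size, 0:size]
        for cx, cy in centers:
            img[(xs - cx) ** 2 + (ys - cy) ** 2 <= radius**2] = 255
        return img

    def test_counts_three_discs(self):
        img = self.disc_image([(20, 20), (50, 60), (80, 30)])
        assert segment_panel(img).n == 3

    def test_two_panel_mode(self):
        a = self.disc_image([(20, 20)])
        b = self.disc_image([(20, 20), (60, 60)])
        seg_a, seg_b = segment(a, "by_panel", image_b=b)
        assert (seg_a.n, seg_b.n) == (1, 2)

    def test_split_line_mode(self):
        img = np.concatenate([self.disc_image([(30, 30)]),
                              self.disc_image([(30, 70), (70, 30)])], axis=1)
        seg_a, seg_b = segment(img, "by_panel", split_x=100)
        assert (seg_a.n, seg_b.n) == (1, 2)

    def test_mixed_colors_partition(self, tmp_path, rng):
        pair = build_pair(PairSpec("D4", 6, 9, "equal_total", "t"), rng=rng)
        paths = render(pair, tmp_path)
        img = np.asarray(Image.open(tmp_path / paths["file_joint"]))
        seg_a, seg_b = segment_colors(img)
        assert {seg_a.n, seg_b.n} == {6, 9}

    def test_centroid_accuracy(self):
        img = self.disc_image([(40, 30)], radius=8)
        seg = segment_panel(img)
        assert seg.centroids[0] == pytest.approx([40, 30], abs=0.1)

    def test_empty_panel_raises(self):
        with pytest.raises(ValueError, match="empty panel"):
            segment_panel(np.zeros((50, 50), dtype=np.uint8))

    def test_generated_counts_recovered(self, d2_run):
        feats = d2_run["features"]
        assert not feats["seg_mismatch"].any()


class TestHashes:
    def test_ahash_constant_image_all_zero(self):
        img = np.full((64, 64), 80, dtype=np.uint8)
        assert hash_avg(img).sum() == 0  # strict > on equal values

    def test_ahash_half_split(self):
        img = np.zeros((8, 8), dtype=np.uint8)
        img[:4] = 255
        bits = hash_avg(img)
        assert bits.sum() == 32
        assert bits[:32].all() and not bits[32:].any()

    def test_ahash_brightness_scale_invariant(self):
        base = np.tile(np.array([40, 100], dtype=np.uint8), (8, 4))
        assert np.array_equal(hash_avg(base), hash_avg(base * 2))

    def test_phash_constant_image(self):
        img = np.full((32, 32), 120, dtype=np.uint8)
        bits = hash_perceptual(img)
        assert bits[0] == 1          # DC above the zero median
        assert bits[1:].sum() == 0   # all AC coefficients are exactly 0

    def test_phash_median_split_popcount(self, rng):
        img = rng.integers(0, 256, size=(64, 64), dtype=np.uint8)
        from scipy.fft import dctn

        from numprops.features import _resample
        coef = dctn(_resample(img, 32), type=2, norm="ortho")[:8, :8]
        assert len(np.unique(coef)) == 64  # distinct => exact median split
        assert hash_perceptual(img).sum() == 32

    def test_phash_ac_bits_shift_invariant(self, rng):
        # DCT linearity: +c moves only the DC coefficient
        img = rng.integers(50, 200, size=(32, 32)).astype(np.uint8)
        h1, h2 = hash_perceptual(img), hash_perceptual(img + 20)
        assert np.array_equal(h1[1:], h2[1:])

    def test_whash_constant_image_ll_only(self):
        img = np.full((8, 8), 90, dtype=np.uint8)
        bits = hash_wavelet(img)
        assert bits[:16].all()        # LL approximation is positive
        assert bits[16:].sum() == 0   # all detail coefficients are 0

    def test_whash_vertical_edge_band(self):
        # Haar oracle: a left/right split off the block boundary yields
        # detail only in the band differencing along x; LL always nonzero
        img = np.zeros((8, 8), dtype=np.uint8)
        img[:, 3:] = 255
        import pywt

        cA, (cH, cV, cD) = pywt.dwt2(np.asarray(img, dtype=float), "haar")
        assert np.allclose(cH, 0) and np.allclose(cD, 0)
        assert not np.allclose(cV, 0)
        # full bit oracle: strict > against the lower median of all 64
        coef = np.concatenate([c.ravel() for c in (cA, cH, cV, cD)])
        med = np.sort(coef)[31]
        assert np.array_equal(hash_wavelet(img), (coef > med).astype(int))

    def test_whash_median_split_popcount(self, rng):
        img = rng.integers(0, 256, size=(8, 8), dtype=np.uint8)
        import pywt
        cA, (cH, cV, cD) = pywt.dwt2(np.asarray(img, dtype=float), "haar")
        coef = np.concatenate([c.ravel() for c in (cA, cH, cV, cD)])
        if len(np.unique(coef)) == 64:
            assert hash_wavelet(img).sum() == 32


class TestHamming:
    def test_identity_and_complement(self, rng):
        h = rng.integers(0, 2, size=64)
        assert hamming(h, h) == 0
        assert hamming(h, 1 - h) == 64

    def test_xor_popcount_oracle(self, rng):
        for _ in range(1000):
            h1 = rng.integers(0, 2, size=64)
            h2 = rng.integers(0, 2, size=64)
            oracle = sum(int(a) ^ int(b) for a, b in zip(h1, h2))
            assert hamming(h1, h2) == oracle

    def test_triangle_inequality(self, rng):
        h1, h2, h3 = (rng.integers(0, 2, size=64) for _ in range(3))
        assert hamming(h1, h3) <= hamming(h1, h2) + hamming(h2, h3)

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            hamming(np.zeros(64), np.zeros(32))


class TestExtractDataset:
    def test_row_and_column_count(self, d2_run):
        feats = d2_run["features"]
        assert len(feats) == 36
        assert feats.columns[:2].tolist() == ["STIMID", "dot_ratio"]
        assert len(feats.columns) == 18  # 17 features + seg_mismatch

    def test_rerun_identical(self, d2_run):
        feats2 = extract_dataset(d2_run["stimlist"], d2_run["pics"])
        assert feats2.equals(d2_run["features"])

    def test_hash_distances_integer_in_range(self, d2_run):
        for col in ("hash_avg", "hash_perc", "hash_wav"):
            vals = d2_run["features"][col]
            assert vals.between(0, 64).all()
            assert (vals == vals.astype(int)).all()

    def test_equal_mean_area_ratio_tracks_dot_ratio(self, d1_run):
        # on equal-mean pairs total area ratio must equal the dot ratio
        merged = d1_run["features"].merge(d1_run["stimlist"], on="STIMID")
        em = merged[merged["area_condition"] == "equal_mean"]
        assert len(em) == 60
        np.testing.assert_allclose(em["area_total"], em["dot_ratio"],
                                   rtol=0.02)
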