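import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vesselseg.thresholding import (
    DegenerateHistogramError,
    EmptyFOVError,
    GrayHistogram,
    apply_threshold,
    build_histogram,
    classify_pixels,
    fuse_wide_into_thin,
    level_to_intensity,
    otsu_threshold,
    region_threshold_map,
)


def brute_force_otsu(counts):
    """Independent exhaustive maximizer of the between-class variance.

    Works from the class definitions directly in exact rational arithmetic:
    for every split t the class probabilities and means are computed by
    explicit summation and sigma2_B from its defining formula
    w0*(mu0-muT)^2 + w1*(mu1-muT)^2; ties go to the smallest t.
    """
    from fractions import Fraction

    counts = [int(c) for c in counts]
    L = len(counts)
    n = sum(counts)
    P = [Fraction(c, n) for c in counts]
    muT = sum(i * p for i, p in enumerate(P))
    best_t, best_v = None, Fraction(-1)
    for t in range(L - 1):
        w0 = sum(P[: t + 1])
        w1 = 1 - w0
        if w0 == 0 or w1 == 0:
            v = Fraction(0)
        else:
            mu0 = sum(i * P[i] for i in range(t + 1)) / w0
            mu1 = sum(i * P[i] for i in range(t + 1, L)) / w1
            v = w0 * (mu0 - muT) ** 2 + w1 * (mu1 - muT) ** 2
        if v > best_v:
            best_v, best_t = v, t
    return best_t


class TestBuildHistogram:
    def test_all_zero_pixels(self):
        h = build_histogram(np.zeros((4, 4)), levels=256)
        assert h.counts[0] == 16 and h.counts[1:].sum() == 0

    def test_two_level_split(self):
        img = np.concatenate([np.zeros(8), np.ones(8)]).reshape(4, 4)
        h = build_histogram(img, levels=256)
        assert h.probabilities[0] == h.probabilities[255] == 0.5

    def test_hand_quantization(self):
        img = np.array([[0.1, 0.1, 0.1], [0.9, 0.9, 0.9]])
        h = build_histogram(img, levels=10)
        # floor(0.1 * 9 + 0.5) = 1, floor(0.9 * 9 + 0.5) = 8
        assert h.counts[1] == 3 and h.counts[8] == 3
        assert h.counts.sum() == 6

    def test_fov_restriction(self):
        img = np.array([[0.0, 1.0], [1.0, 1.0]])
        fov = np.array([[1, 0], [0, 0]])
        h = build_histogram(img, fov=fov, levels=4)
        assert h.n == 1 and h.counts[0] == 1

    def test_empty_fov(self):
        with pytest.raises(EmptyFOVError):
            build_histogram(np.zeros((3, 3)), fov=np.zeros((3, 3)))


class TestOtsuThreshold:
    def test_two_cluster_histogram_smallest_tie(self):
        counts = np.zeros(10, dtype=int)
        counts[1], counts[8] = 3, 3
        t, _ = otsu_threshold(GrayHistogram(counts=counts, levels=10))
        assert t == 1  # all t in 1..7 give equal variance; smallest wins

    def test_perfectly_separable_spikes(self):
        counts = np.zeros(16, dtype=int)
        counts[0], counts[15] = 5, 5
        t, stats = otsu_threshold(GrayHistogram(counts=counts, levels=16))
        assert t == 0
        assert stats.omega0 == stats.omega1 == 0.5
        assert stats.sigma2_W == pytest.approx(0.0, abs=1e-12)
        assert stats.beta == pytest.approx(1.0)

    def test_degenerate_single_level(self):
        counts = np.zeros(8, dtype=int)
        counts[3] = 10
        with pytest.raises(DegenerateHistogramError):
            otsu_threshold(GrayHistogram(counts=counts, levels=8))

    @given(
        counts=st.lists(st.integers(0, 50), min_size=2, max_size=32).filter(
            lambda c: sum(1 for x in c if x > 0) >= 2
        )
    )
    @settings(max_examples=300, deadline=None, derandomize=True)
    def test_matches_brute_force(self, counts):
        counts = np.asarray(counts)
        hist = GrayHistogram(counts=counts, levels=len(counts))
        t, _ = otsu_threshold(hist)
        assert t == brute_force_otsu(counts)

    @given(
        counts=st.lists(st.integers(0, 50), min_size=3, max_size=24).filter(
            lambda c: sum(1 for x in c if x > 0) >= 2
        )
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_variance_decomposition_at_every_split(self, counts):
        from vesselseg.thresholding import _stats_at

        counts = np.asarray(counts, dtype=float)
        P = counts / counts.sum()
        for t in range(len(counts) - 1):
            s = _stats_at(P, t)
            assert s.sigma2_B + s.sigma2_W == pytest.approx(
                s.sigma2_T, rel=1e-9, abs=1e-12
            )
            assert 0.0 <= s.beta <= 1.0 + 1e-12
            assert s.omega0 + s.omega1 == pytest.approx(1.0)


class TestApplyThreshold:
    def test_zero_threshold_selects_all(self):
        assert apply_threshold(np.random.default_rng(0).random((4, 4)), 0.0).all()

    def test_above_max_selects_none(self):
        assert not apply_threshold(np.full((3, 3), 0.4), 0.5).any()

    def test_boundary_inclusive(self):
        img = np.array([[0.2, 0.5, 0.8]])
        np.testing.assert_array_equal(
            apply_threshold(img, 0.5), np.array([[0, 1, 1]])
        )

    def test_level_to_intensity(self):
        assert level_to_intensity(255, 256) == 1.0
        assert level_to_intensity(0, 256) == 0.0


class TestFusion:
    def test_empty_wide_mask_is_identity(self, rng):
        thin = rng.random((6, 6))
        np.testing.assert_array_equal(
            fuse_wide_into_thin(thin, np.zeros((6, 6))), thin
        )

    def test_full_wide_mask_saturates(self, rng):
        out = fuse_wide_into_thin(rng.random((5, 5)), np.ones((5, 5)))
        assert np.all(out == 1.0)

    def test_blob_saturated_rest_untouched(self):
        thin = np.full((8, 8), 0.3)
        wide = np.zeros((8, 8))
        wide[2:4, 2:4] = 1
        out = fuse_wide_into_thin(thin, wide)
        assert np.all(out[2:4, 2:4] == 1.0)
        assert np.all(out[5:, 5:] == 0.3)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            fuse_wide_into_thin(np.zeros((4, 4)), np.zeros((5, 5)))


class TestRegionThresholdMap:
    def test_zero_offset_uniform(self):
        tmap = region_threshold_map(0.5, np.zeros((6, 6)), offset=0.0, radius=3)
        assert np.all(tmap.values == 0.5)

    def test_empty_wide_mask_lowers_everywhere(self):
        tmap = region_threshold_map(0.5, np.zeros((6, 6)), offset=0.1, radius=3)
        assert np.all(tmap.values == pytest.approx(0.4))

    def test_single_pixel_disk_footprint(self):
        wide = np.zeros((9, 9))
        wide[4, 4] = 1
        tmap = region_threshold_map(0.5, wide, offset=0.05, radius=2)
        high = tmap.values == pytest.approx(0.55)
        # disk of radius 2: 13 integer offsets with dx^2+dy^2 <= 4
        assert np.count_nonzero(np.isclose(tmap.values, 0.55)) == 13
        assert np.count_nonzero(np.isclose(tmap.values, 0.45)) == 81 - 13

    def test_clamped_to_unit_interval(self):
        wide = np.ones((3, 3))
        tmap = region_threshold_map(0.98, wide, offset=0.1, radius=1)
        assert tmap.values.max() <= 1.0


class TestClassifyPixels:
    def test_all_zero(self):
        tmap = region_threshold_map(0.5, np.zeros((4, 4)), 0.05, 2)
        assert not classify_pixels(np.zeros((4, 4)), tmap, np.zeros((4, 4))).any()

    def test_wide_pixels_always_kept(self, rng):
        wide = (rng.random((8, 8)) > 0.5).astype(np.uint8)
        fused = fuse_wide_into_thin(rng.random((8, 8)) * 0.2, wide)
        tmap = region_threshold_map(0.9, wide, 0.05, 2)
        out = classify_pixels(fused, tmap, wide)
        assert np.all(out[wide > 0] == 1)  # superset of the wide mask

    def test_faint_line_kept_only_far_from_blob(self):
        # 8x8: wide blob upper-left; faint thin line at 0.48 crossing the frame
        wide = np.zeros((8, 8))
        wide[0:2, 0:2] = 1
        thin = np.zeros((8, 8))
        thin[:, 6] = 0.48
        fused = fuse_wide_into_thin(thin, wide)
        tmap = region_threshold_map(0.5, wide, offset=0.05, radius=2)
        out = classify_pixels(fused, tmap, wide)
        # outside the blob neighborhood the threshold is 0.45 -> line kept
        assert np.all(out[:, 6] == 1)
        # inside the neighborhood the threshold is 0.55 -> 0.48 rejected
        assert out[2, 2] == 0

    def test_offset_monotonicity(self, rng):
        wide = np.zeros((16, 16))
        wide[7, 7] = 1
        fused = rng.random((16, 16))
        lo = region_threshold_map(0.5, wide, 0.02, 3)
        hi = region_threshold_map(0.5, wide, 0.10, 3)
        out_lo = classify_pixels(fused, lo, wide)
        out_hi = classify_pixels(fused, hi, wide)
        neighborhood = np.isclose(hi.values, 0.6)
        # larger offset: fewer vessels inside N, more outside
        assert np.all(out_hi[neighborhood] <= out_lo[neighborhood])
        assert np.all(out_hi[~neighborhood] >= out_lo[~neighborhood])
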