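import numpy as np
import pytest

from vasculomorph import (LandmarkSet, Volume3D, compare_invivo_exvivo,
                          fv_correlation, resample, tps_fit, warp_volume)


def random_landmarks(n=8, seed=0):
    rng = np.random.default_rng(seed)
    return rng.uniform(0, 100, (n, 3))


class TestTPS:
    def test_identity_landmarks_identity_transform(self):
        src = random_landmarks()
        warp = tps_fit(LandmarkSet(src, src.copy()))
        pts = random_landmarks(20, seed=1)
        assert np.allclose(warp(pts), pts, atol=1e-8)

    def test_zero_regularization_interpolates_exactly(self):
        src = random_landmarks(10, seed=2)
        rng = np.random.default_rng(3)
        tgt = src + rng.normal(0, 5, src.shape)
        warp = tps_fit(LandmarkSet(src, tgt), regularization=0.0)
        assert np.abs(warp(src) - tgt).max() < 1e-8

    def test_affine_landmarks_reproduce_affine_on_held_out_points(self):
        src = random_landmarks(10, seed=4)
        a = np.array([[1.2, 0.1, -0.05], [0.0, 0.9, 0.2], [0.1, 0.0, 1.1]])
        t = np.array([10.0, -4.0, 7.0])
        warp = tps_fit(LandmarkSet(src, src @ a.T + t))
        held = random_landmarks(64, seed=5)
        assert np.abs(warp(held) - (held @ a.T + t)).max() < 1e-6

    def test_coplanar_landmarks_rejected(self):
        src = random_landmarks(6, seed=6)
        src[:, 2] = 3.0
        with pytest.raises(ValueError, match="coplanar"):
            LandmarkSet(src, src.copy())

    def test_duplicate_source_rejected(self):
        src = random_landmarks(5, seed=7)
        src[1] = src[0]
        with pytest.raises(ValueError, match="duplicate"):
            LandmarkSet(src, src.copy())

    def test_too_few_landmarks_rejected(self):
        src = random_landmarks(3, seed=8)
        with pytest.raises(ValueError, match="4 landmark"):
            LandmarkSet(src, src.copy())


class TestWarpVolume:
    def _identity_warp(self, bbox=100.0):
        src = np.array([[0, 0, 0], [bbox, 0, 0], [0, bbox, 0], [0, 0, bbox],
                        [bbox, bbox, bbox]], dtype=float)
        return tps_fit(LandmarkSet(src, src.copy()))

    def test_identity_warp_preserves_volume(self):
        rng = np.random.default_rng(9)
        vol = Volume3D(rng.uniform(0, 1, (10, 10, 10)), spacing=(5.0,) * 3)
        out = warp_volume(vol, self._identity_warp(50.0), vol, interp="linear")
        assert np.allclose(np.asarray(out.data), np.asarray(vol.data), atol=1e-6)

    def test_one_voxel_translation_nearest(self):
        src = np.array([[0, 0, 0], [90, 0, 0], [0, 90, 0], [0, 0, 90],
                        [90, 90, 90]], dtype=float)
        warp = tps_fit(LandmarkSet(src, src + np.array([10.0, 0.0, 0.0])))
        data = np.zeros((10, 10, 10), dtype=np.uint8)
        data[4, 5, 5] = 1
        vol = Volume3D(data, spacing=(10.0,) * 3, kind="binary")
        out = warp_volume(vol, warp, vol, interp="nearest")
        # backward mapping by +1 voxel in x pulls the source from x+1
        assert np.asarray(out.data)[3, 5, 5] == 1

    def test_linear_interp_on_binary_rejected(self):
        vol = Volume3D(np.zeros((5, 5, 5), dtype=np.uint8), kind="binary")
        with pytest.raises(ValueError, match="nearest"):
            warp_volume(vol, self._identity_warp(), vol, interp="linear")

    def test_small_smooth_warp_nearly_conserves_mask_volume(self):
        rng = np.random.default_rng(10)
        src = rng.uniform(0, 100, (10, 3))
        tgt = src + rng.normal(0, 1.0, src.shape)  # near-rigid perturbation
        warp = tps_fit(LandmarkSet(src, tgt))
        data = np.zeros((20, 20, 20), dtype=np.uint8)
        data[6:14, 6:14, 6:14] = 1
        vol = Volume3D(data, spacing=(5.0,) * 3, kind="binary")
        out = warp_volume(vol, warp, vol, interp="nearest")
        v_in, v_out = data.sum(), np.asarray(out.data).sum()
        assert abs(v_out - v_in) / v_in <= 0.10


class TestResample:
    def test_checkerboard_mean_bin_uniform_half(self):
        ii, jj, kk = np.meshgrid(*[np.arange(8)] * 3, indexing="ij")
        board = ((ii + jj + kk) % 2).astype(np.uint8)
        vol = Volume3D(board, kind="binary")
        out = resample(vol, (2, 2, 2), mode="mean-bin")
        assert np.allclose(np.asarray(out.data), 0.5)

    def test_upsample_then_downsample_identity_on_integers(self):
        rng = np.random.default_rng(11)
        data = rng.integers(0, 5, (6, 6, 6)).astype(float)
        vol = Volume3D(data)
        up = resample(vol, (-2, -2, -2))
        back = resample(up, (2, 2, 2), mode="mean-bin")
        assert np.array_equal(np.asarray(back.data), data)

    def test_mean_bin_conserves_mass(self):
        rng = np.random.default_rng(12)
        vol = Volume3D(rng.uniform(0, 1, (12, 12, 12)), spacing=(4.0,) * 3)
        out = resample(vol, (3, 3, 3), mode="mean-bin")
        mass_in = np.asarray(vol.data).sum() * vol.voxel_volume
        mass_out = np.asarray(out.data).sum() * out.voxel_volume
        assert mass_out == pytest.approx(mass_in, rel=1e-6)

    def test_thin_tube_partial_volume_inflation(self):
        from tests.conftest import make_tube
        _, fine = make_tube(1.6, 56.0, shape=(64, 64, 64))
        fv_fine = float(np.asarray(fine.data).mean())
        coarse = resample(fine, (2, 2, 2), mode="mean-bin")
        fv_coarse = float((np.asarray(coarse.data) >= 0.5).mean())
        assert fv_coarse > fv_fine


class TestFVCorrelation:
    def test_identical_grids_perfect_correlation(self):
        rng = np.random.default_rng(13)
        fv = rng.uniform(0, 0.2, (8, 8, 8))
        rep = fv_correlation(fv, fv.copy())
        assert rep.r == pytest.approx(1.0)
        assert rep.slope == pytest.approx(1.0)
        assert rep.intercept == pytest.approx(0.0, abs=1e-12)

    def test_doubled_signal_slope_two(self):
        rng = np.random.default_rng(14)
        fv = rng.uniform(0, 0.2, 512)
        rep = fv_correlation(fv, 2 * fv + 1e-9 * rng.standard_normal(512))
        assert rep.slope == pytest.approx(2.0, rel=1e-4)
        assert rep.r > 0.9999

    def test_independent_grids_near_zero_r(self):
        hits = 0
        n_rep = 200
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            a = rng.uniform(0, 0.2, 512)
            b = rng.uniform(0, 0.2, 512)
            if abs(fv_correlation(a, b).r) < 0.15:
                hits += 1
        assert hits / n_rep >= 0.95

    def test_matches_brute_force_covariance(self):
        rng = np.random.default_rng(15)
        a = rng.uniform(0, 1, 256)
        b = 0.4 * a + rng.normal(0, 0.1, 256)
        rep = fv_correlation(a, b)
        cov = ((a - a.mean()) * (b - b.mean())).mean()
        r_brute = cov / (a.std() * b.std())
        assert rep.r == pytest.approx(r_brute, abs=1e-12)

    def test_zero_variance_r_undefined(self):
        rep = fv_correlation(np.full(10, 0.1), np.arange(10.0))
        assert np.isnan(rep.r)

    def test_band_widens_away_from_mean(self):
        rng = np.random.default_rng(16)
        a = rng.uniform(0, 1, 128)
        rep = fv_correlation(a, a + rng.normal(0, 0.1, 128))
        width = rep.band["hi95"] - rep.band["lo95"]
        assert width.iloc[0] > width.iloc[len(width) // 2]


class TestCompareInvivoExvivo:
    def _volumes(self):
        shape = (16, 16, 16)
        ii, jj, kk = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
        tumor = ((ii - 8) ** 2 + (jj - 8) ** 2 + (kk - 8) ** 2 <= 16)
        contra = ~tumor
        rng = np.random.default_rng(17)
        dcbv = Volume3D(0.01 + 0.05 * tumor + 0.002 * rng.standard_normal(shape),
                        kind="parametric")
        fv = Volume3D(0.03 + 0.06 * tumor + 0.002 * rng.standard_normal(shape),
                      kind="parametric")
        t = Volume3D(tumor.astype(np.uint8), kind="binary")
        c = Volume3D(contra.astype(np.uint8), kind="binary")
        return dcbv, fv, t, c

    def test_elevated_tumor_medians(self):
        dcbv, fv, t, c = self._volumes()
        out = compare_invivo_exvivo(dcbv, fv, t, c)
        assert out["rois"]["tumor"]["median_dcbv"] > out["rois"]["contralateral"]["median_dcbv"]
        assert out["rois"]["tumor"]["median_fv"] > out["rois"]["contralateral"]["median_fv"]

    def test_2d_histogram_marginals_match_1d(self):
        dcbv, fv, t, c = self._volumes()
        out = compare_invivo_exvivo(dcbv, fv, t, c)
        h2 = out["hist2d"]
        union_d = out["rois"]["tumor"]["dcbv_hist"] + out["rois"]["contralateral"]["dcbv_hist"]
        union_f = out["rois"]["tumor"]["fv_hist"] + out["rois"]["contralateral"]["fv_hist"]
        assert np.array_equal(h2.sum(axis=1), union_d)
        assert np.array_equal(h2.sum(axis=0), union_f)

    def test_constant_fv_single_bin(self):
        dcbv, _, t, c = self._volumes()
        fv_const = dcbv.with_data(np.full(dcbv.shape, 0.1))
        out = compare_invivo_exvivo(dcbv, fv_const, t, c)
        for roi in out["rois"].values():
            assert (roi["fv_hist"] > 0).sum() == 1

    def test_empty_roi_rejected(self):
        dcbv, fv, t, _ = self._volumes()
        empty = t.with_data(np.zeros(t.shape, dtype=np.uint8))
        with pytest.raises(ValueError, match="empty ROI"):
            compare_invivo_exvivo(dcbv, fv, t, empty)
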