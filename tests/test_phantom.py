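import dataclasses
import math

import numpy as np
import pytest
from scipy import ndimage

from vasculomorph import (PhantomSpec, SignalParams, ZoneParams, fit_tensor,
                          generate_vessel_tree, ground_truth_morphometry,
                          rasterize_tree, simulate_dwi, simulate_mge)
from vasculomorph.dti import GradientScheme
from vasculomorph.phantom import Segment, VesselTree, capsule_volume


def tree_equal(a: VesselTree, b: VesselTree) -> bool:
    if len(a) != len(b):
        return False
    return all(
        np.allclose(x.p_start, y.p_start) and np.allclose(x.p_end, y.p_end)
        and x.radius == y.radius and x.zone == y.zone and x.parent == y.parent
        for x, y in zip(a.segments, b.segments)
    )


class TestGenerateVesselTree:
    def test_same_spec_same_seed_identical(self, small_phantom_spec):
        t1 = generate_vessel_tree(small_phantom_spec)
        t2 = generate_vessel_tree(small_phantom_spec)
        assert tree_equal(t1, t2)

    def test_zero_tumor_radius_all_normal(self, small_phantom_spec):
        spec = dataclasses.replace(small_phantom_spec, tumor_radius_um=0.0)
        tree = generate_vessel_tree(spec)
        assert set(tree.zones()) == {"normal"}

    def test_tumor_segments_shorter_when_specified(self):
        # tumor mean length set to half of normal; compare realized means
        spec = PhantomSpec(
            domain_size_um=(3000.0,) * 3, spacing_um=(31.0,) * 3,
            tumor_center_um=(1500.0,) * 3, tumor_radius_um=900.0,
            transition_width_um=200.0,
            normal=ZoneParams(length_mean_um=300, length_sd_um=100, target_fv=0.04),
            tumor=ZoneParams(length_mean_um=150, length_sd_um=50, target_fv=0.1),
            seed=11,
        )
        tree = generate_vessel_tree(spec)
        lengths = {z: [s.length for s in tree.segments if s.zone == z]
                   for z in ("normal", "tumor")}
        assert len(lengths["normal"]) + len(lengths["tumor"]) >= 200
        assert np.mean(lengths["tumor"]) < np.mean(lengths["normal"])

    def test_realized_fv_within_20pct_of_target(self, small_phantom_spec):
        tree = generate_vessel_tree(small_phantom_spec)
        _, fv = ground_truth_morphometry(tree, small_phantom_spec, mc_samples=100_000)
        for z in ("normal", "transition", "tumor"):
            target = small_phantom_spec.zone_params(z).target_fv
            assert abs(fv[z] - target) / target < 0.20, (z, fv[z], target)

    def test_unreachable_target_raises(self):
        spec = PhantomSpec(domain_size_um=(500.0,) * 3, spacing_um=(31.0,) * 3,
                           tumor_radius_um=0.0,
                           normal=ZoneParams(radius_mean_um=1.0, radius_sd_um=0.01,
                                             length_mean_um=5.0, length_sd_um=1.0,
                                             target_fv=0.45),
                           seed=0)
        with pytest.raises(RuntimeError, match="attempts"):
            generate_vessel_tree(spec, max_attempts=500)

    def test_children_start_on_parent(self, small_phantom_spec):
        tree = generate_vessel_tree(small_phantom_spec)
        for s in tree.segments:
            if s.parent >= 0:
                parent = tree.segments[s.parent]
                assert np.linalg.norm(s.p_start - parent.p_end) <= max(
                    small_phantom_spec.spacing_um)


class TestRasterize:
    def test_cylinder_voxel_count_near_analytic(self):
        # radius 3, length 20 voxels at unit spacing
        tree = VesselTree([Segment(np.array([5.0, 16, 16]),
                                   np.array([25.0, 16, 16]), 3.0, "normal")])
        binary, _, _ = rasterize_tree(tree, (32, 32, 32), (1.0, 1.0, 1.0))
        analytic = capsule_volume(3.0, 20.0)
        count = int(np.asarray(binary.data).sum())
        assert abs(count - analytic) / analytic < 0.10

    def test_empty_tree_all_zero(self):
        binary, labels, radius = rasterize_tree(VesselTree([]), (8, 8, 8), (1, 1, 1))
        assert not np.asarray(binary.data).any()
        assert not np.asarray(labels.data).any()

    def test_two_disjoint_segments_two_components(self):
        tree = VesselTree([
            Segment(np.array([4.0, 8, 8]), np.array([20.0, 8, 8]), 2.0, "normal"),
            Segment(np.array([4.0, 24, 24]), np.array([20.0, 24, 24]), 2.0, "normal"),
        ])
        binary, _, _ = rasterize_tree(tree, (32, 32, 32), (1, 1, 1))
        _, n = ndimage.label(np.asarray(binary.data),
                             structure=ndimage.generate_binary_structure(3, 3))
        assert n == 2

    def test_rasterization_converges_with_resolution(self):
        # voxel-count/analytic ratio approaches 1 as spacing shrinks
        tree = VesselTree([Segment(np.array([50.0, 100, 100]),
                                   np.array([150.0, 100, 100]), 20.0, "normal")])
        analytic = capsule_volume(20.0, 100.0)
        ratios = []
        for spacing, shape in ((10.0, (20, 20, 20)), (4.0, (50, 50, 50))):
            b, _, _ = rasterize_tree(tree, shape, (spacing,) * 3)
            ratios.append(int(np.asarray(b.data).sum()) * spacing**3 / analytic)
        assert abs(ratios[1] - 1) < abs(ratios[0] - 1) or abs(ratios[1] - 1) < 0.02


class TestSimulateMGE:
    def test_noiseless_tissue_closed_form(self, unit_tube):
        _, binary = unit_tube
        params = SignalParams(echo_times_ms=(4.9, 9.7), s0_tissue=1000.0,
                              r2star_tissue=0.05, rim_width_vox=0)
        echoes = simulate_mge(binary, params)
        tissue = np.asarray(binary.data) == 0
        assert np.allclose(np.asarray(echoes[0].data)[tissue],
                           1000.0 * math.exp(-0.245))

    def test_vessel_voxels_zero_at_all_echoes(self, unit_tube):
        _, binary = unit_tube
        echoes = simulate_mge(binary, SignalParams(s0_vessel=0.0))
        inside = np.asarray(binary.data) > 0
        for e in echoes:
            assert np.all(np.asarray(e.data)[inside] == 0.0)

    def test_rim_darker_than_far_tissue(self, unit_tube):
        _, binary = unit_tube
        params = SignalParams(rim_width_vox=1, rim_delta_r2star=0.03)
        echoes = simulate_mge(binary, params)
        v = np.asarray(binary.data) > 0
        rim = ndimage.binary_dilation(v) & ~v
        far = ~ndimage.binary_dilation(v, iterations=3)
        e = np.asarray(echoes[-1].data)
        assert e[rim].max() < e[far].min()

    def test_negative_snr_rejected(self, unit_tube):
        _, binary = unit_tube
        with pytest.raises(ValueError, match="SNR"):
            simulate_mge(binary, SignalParams(), noise="rician", snr=-5.0)


class TestSimulateDWI:
    def test_isotropic_tensor_identical_dwis(self):
        tens = np.tile(np.eye(3) * 7e-4, (4, 4, 4, 1, 1))
        _, dwis = simulate_dwi(tens, SignalParams())
        ref = np.asarray(dwis[0].data)
        for d in dwis[1:]:
            assert np.allclose(np.asarray(d.data), ref)

    def test_stick_tensor_no_signal_loss_orthogonal(self):
        # diffusion only along x: the [0,1,1] direction sees no attenuation
        lam = 1.5e-3
        tens = np.tile(np.diag([lam, 0.0, 0.0]), (3, 3, 3, 1, 1))
        params = SignalParams(b_value=1700.0)
        b0, dwis = simulate_dwi(tens, params, s0=500.0)
        dirs = np.asarray(params.directions, dtype=float)
        i_xy = next(i for i, g in enumerate(dirs) if tuple(g) == (1, 1, 0))
        i_yz = next(i for i, g in enumerate(dirs) if tuple(g) == (0, 1, 1))
        assert np.allclose(np.asarray(dwis[i_yz].data), 500.0)
        assert np.allclose(np.asarray(dwis[i_xy].data),
                           500.0 * np.exp(-1700.0 * lam / 2.0))

    def test_fit_recovers_simulated_tensor(self):
        rng = np.random.default_rng(7)
        a = rng.standard_normal((3, 3))
        d = (a @ a.T) * 2e-4
        tens = np.tile(d, (3, 3, 3, 1, 1))
        scheme = GradientScheme()
        b0, dwis = simulate_dwi(tens, SignalParams())
        field = fit_tensor(b0, dwis, scheme)
        assert np.abs(field.tensors[1, 1, 1] - d).max() <= 1e-8 * np.abs(d).max()

    def test_non_psd_tensor_rejected(self):
        tens = np.tile(np.diag([1e-3, -1e-4, 1e-4]), (2, 2, 2, 1, 1))
        with pytest.raises(ValueError, match="positive"):
            simulate_dwi(tens, SignalParams())


class TestGroundTruth:
    def test_single_segment_length(self, small_phantom_spec):
        tree = VesselTree([Segment(np.array([0.0, 0, 0]),
                                   np.array([0.0, 0, 300]), 30.0, "normal")])
        table, _ = ground_truth_morphometry(tree, small_phantom_spec, mc_samples=1000)
        assert table["length_um"].iloc[0] == pytest.approx(300.0)

    def test_single_capsule_fv_closed_form(self):
        spec = PhantomSpec(domain_size_um=(1000.0,) * 3, spacing_um=(31.0,) * 3,
                           tumor_radius_um=0.0)
        tree = VesselTree([Segment(np.array([200.0, 500, 500]),
                                   np.array([500.0, 500, 500]), 30.0, "normal")])
        _, fv = ground_truth_morphometry(tree, spec, mc_samples=1000)
        expected = (math.pi * 30**2 * 300 + 4 / 3 * math.pi * 30**3) / 1e9
        assert fv["total"] == pytest.approx(expected)

    def test_no_tumor_segments_zero_tumor_fv(self, small_phantom_spec):
        # one vessel far from the tumor sphere
        tree = VesselTree([Segment(np.array([100.0, 100, 100]),
                                   np.array([400.0, 100, 100]), 30.0, "normal")])
        _, fv = ground_truth_morphometry(tree, small_phantom_spec, mc_samples=50_000)
        assert fv["tumor"] == 0.0

    def test_partial_volume_overestimates_fv_on_coarse_grid(self):
        # the same thin tree segmented at 2x coarser spacing reports more FV
        from vasculomorph import resample
        tree = VesselTree([
            Segment(np.array([6.0, 16, 16]), np.array([58.0, 16, 16]), 1.6, "normal"),
            Segment(np.array([6.0, 40, 44]), np.array([58.0, 44, 40]), 1.8, "normal"),
        ])
        fine, _, _ = rasterize_tree(tree, (64, 64, 64), (1.0, 1.0, 1.0))
        fv_fine = float(np.asarray(fine.data).mean())
        coarse = resample(fine, (2, 2, 2), mode="mean-bin")
        fv_coarse = float((np.asarray(coarse.data) >= 0.5).mean())
        assert fv_coarse > fv_fine
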