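"""Skeleton morphometry: layers, volumes, directions, radii, branches."""

import numpy as np
import pytest

from paskin import (
    VoxelGrid,
    count_branches,
    cross_section_radius,
    determine_analysis_depth,
    digital_cylinder,
    local_direction,
    mean_so2_per_layer,
    mean_thickness,
    melanin_volume,
    partition_layers,
    skeletonize,
    structure_volume,
)
from paskin.morphometry import LayerPartition
from paskin.segmentation import BinaryStructure
from paskin.unmixing import SO2Map

SP = (30.0, 30.0, 30.0)


class TestLayerPartition:
    def test_nine_slices_split_evenly(self):
        p = partition_layers(9)
        assert p.boundaries == (0, 3, 6, 9)
        assert p.layer_range(1) == (0, 3)
        assert p.layer_range(3) == (6, 9)

    def test_ten_slices_remainder_to_last(self):
        assert partition_layers(10).boundaries == (0, 3, 6, 10)

    @pytest.mark.parametrize("d", range(3, 201))
    def test_widths_differ_by_at_most_one(self, d):
        p = partition_layers(d)
        widths = np.diff(p.boundaries)
        assert widths.sum() == d
        assert widths.max() - widths.min() <= 1

    def test_too_shallow_refused(self):
        with pytest.raises(ValueError):
            partition_layers(2)


class TestVolumes:
    def test_empty_mask_zero(self):
        assert structure_volume(np.zeros((5, 5, 5), bool)) == 0

    def test_truth_mask_full_depth_equals_truth(self, tree_truth):
        assert structure_volume(tree_truth.vessel_mask) == tree_truth.vessel_volume_voxels

    def test_layer_volumes_sum_to_total(self, tree_truth):
        p = partition_layers(tree_truth.grid.nz)
        parts = [structure_volume(tree_truth.vessel_mask, p.layer_range(k)) for k in (1, 2, 3)]
        assert sum(parts) == tree_truth.vessel_volume_voxels

    def test_out_of_range_layer_refused(self):
        with pytest.raises(ValueError):
            structure_volume(np.zeros((5, 5, 5), bool), (0, 9))

    def test_melanin_volume_units(self):
        mask = np.zeros((4, 4, 4), bool)
        mask[0, 0, :2] = True
        vox, um3 = melanin_volume(mask, SP)
        assert vox == 2
        assert um3 == pytest.approx(2 * 27000.0)


class TestSkeleton:
    def test_single_voxel_survives(self):
        mask = np.zeros((9, 9, 9), bool)
        mask[4, 4, 4] = True
        sk = skeletonize(mask, SP, compute_radii=False)
        assert len(sk) == 1
        assert tuple(sk.voxels[0]) == (4, 4, 4)

    def test_cylinder_skeleton_follows_axis(self, grid):
        mask = digital_cylinder(grid, 4.0, axis="x", length_vox=80)
        sk = skeletonize(mask, grid.spacing_um, compute_radii=False)
        assert len(sk) > 40
        # distance of each skeleton voxel to the analytic axis (z0, y0 fixed)
        center = (np.floor(np.asarray(grid.shape) / 2.0) + 0.5) * 30.0
        pos = (sk.voxels + 0.5) * 30.0
        dist_vox = np.hypot(pos[:, 0] - center[0], pos[:, 1] - center[1]) / 30.0
        assert np.mean(dist_vox <= 1.0) >= 0.95

    def test_every_skeleton_voxel_inside_mask(self, tree_truth):
        sk = skeletonize(tree_truth.vessel_mask, SP, compute_radii=False)
        for v in sk.voxels:
            assert tree_truth.vessel_mask[tuple(v)]

    def test_even_symmetric_cylinder_not_annihilated(self):
        """Thinning guard: even-diameter bars must keep a centerline."""
        mask = np.zeros((10, 10, 40), bool)
        mask[4:6, 4:6, 5:35] = True
        sk = skeletonize(mask, SP, compute_radii=False)
        assert len(sk) >= 20


class TestDirections:
    def test_straight_x_segment(self, grid):
        mask = digital_cylinder(grid, 3.0, axis="x", length_vox=60)
        sk = skeletonize(mask, grid.spacing_um, compute_radii=False)
        mid = sk.voxels[np.argsort(sk.voxels[:, 2])[len(sk) // 2]]
        d = local_direction(sk, tuple(mid))
        assert d @ np.array([0.0, 0.0, 1.0]) == pytest.approx(1.0, abs=1e-6)

    def test_diagonal_segment_in_plane(self):
        mask = np.zeros((9, 40, 40), bool)
        for i in range(3, 36):
            mask[3:6, i, i] = True
            mask[3:6, i + 1, i] = True  # 2-wide band so thinning keeps a line
        sk = skeletonize(mask, SP, compute_radii=False)
        mid = sk.voxels[len(sk) // 2]
        d = local_direction(sk, tuple(mid))
        assert abs(d[1]) == pytest.approx(1 / np.sqrt(2), abs=0.1)
        assert abs(d[2]) == pytest.approx(1 / np.sqrt(2), abs=0.1)

    def test_helix_directions_near_analytic_tangent(self):
        """Direction within 10° of the helix tangent for ≥90% of voxels."""
        grid = VoxelGrid(shape=(48, 64, 64), spacing_um=SP)
        t = np.linspace(0, 3 * np.pi, 120)
        R, pitch = 600.0, 150.0  # µm
        center = np.array([720.0, 960.0, 960.0])
        pts = np.stack(
            [center[0] + pitch * t / (2 * np.pi) * 2, center[1] + R * np.sin(t), center[2] + R * np.cos(t)],
            axis=1,
        )
        poly = np.hstack([pts, np.full((len(t), 1), 75.0)])
        from paskin.phantom import rasterize_polylines

        mask = rasterize_polylines(grid, [poly])
        sk = skeletonize(mask, SP, compute_radii=False)
        # analytic tangent at the nearest helix sample
        tang = np.gradient(pts, axis=0)
        tang /= np.linalg.norm(tang, axis=1, keepdims=True)
        good = 0
        total = 0
        for i, v in enumerate(sk.voxels):
            if not sk.direction_valid[i]:
                continue
            p = (v + 0.5) * 30.0
            j = np.argmin(np.linalg.norm(pts - p, axis=1))
            cosang = abs(float(sk.direction[i] @ tang[j]))
            good += cosang >= np.cos(np.deg2rad(10.0))
            total += 1
        assert total > 50
        assert good / total >= 0.9

    def test_isolated_voxel_direction_flagged(self):
        mask = np.zeros((9, 9, 9), bool)
        mask[4, 4, 4] = True
        sk = skeletonize(mask, SP, compute_radii=False)
        with pytest.raises(ValueError, match="undefined"):
            local_direction(sk, (4, 4, 4))

    def test_non_skeleton_voxel_refused(self, tree_truth):
        sk = skeletonize(tree_truth.vessel_mask, SP, compute_radii=False)
        with pytest.raises(ValueError, match="not a skeleton voxel"):
            local_direction(sk, (0, 0, 0))


class TestCrossSectionRadius:
    def test_cylinder_radius_five(self, grid):
        mask = digital_cylinder(grid, 5.0, axis="x", length_vox=80)
        center = tuple(int(np.floor(n / 2.0)) for n in grid.shape)
        r = cross_section_radius(mask, center, np.array([0.0, 0.0, 1.0]), SP)
        assert r / 30.0 == pytest.approx(5.0, abs=0.6)

    def test_single_voxel_radius(self):
        mask = np.zeros((9, 9, 9), bool)
        mask[4, 4, 4] = True
        r = cross_section_radius(mask, (4, 4, 4), np.array([0.0, 0.0, 1.0]), SP)
        assert r / 30.0 == pytest.approx(np.sqrt(1 / np.pi), abs=0.15)

    def test_antiparallel_directions_identical(self, grid):
        mask = digital_cylinder(grid, 4.0, axis="y", length_vox=80)
        center = tuple(int(np.floor(n / 2.0)) for n in grid.shape)
        d = np.array([0.0, 1.0, 0.0])
        assert cross_section_radius(mask, center, d, SP) == cross_section_radius(
            mask, center, -d, SP
        )

    def test_center_outside_mask_refused(self, grid):
        mask = digital_cylinder(grid, 4.0, axis="x", length_vox=40)
        with pytest.raises(ValueError, match="outside"):
            cross_section_radius(mask, (0, 0, 0), np.array([0.0, 0.0, 1.0]), SP)


class TestThickness:
    def test_constant_radius_recovered(self, grid):
        mask = digital_cylinder(grid, 4.0, axis="x", length_vox=80)
        sk = skeletonize(mask, grid.spacing_um)
        assert mean_thickness(sk) == pytest.approx(120.0, rel=0.12)

    def test_two_cylinder_mean(self, grid):
        """Radii 3 and 6 voxels, equal lengths → mean ≈ 4.5 voxels."""
        m1 = digital_cylinder(grid, 3.0, axis="x", length_vox=80, center_offset_vox=(18, 0))
        m2 = digital_cylinder(grid, 6.0, axis="x", length_vox=80, center_offset_vox=(-18, 0))
        sk = skeletonize(m1 | m2, grid.spacing_um)
        assert mean_thickness(sk) / 30.0 == pytest.approx(4.5, abs=0.55)

    def test_empty_layer_is_missing_not_zero(self, grid):
        mask = digital_cylinder(grid, 4.0, axis="x", length_vox=60)
        sk = skeletonize(mask, grid.spacing_um)
        assert mean_thickness(sk, layer_range=(0, 2)) is None


class TestBranches:
    def test_straight_tube_has_none(self, tube_truth):
        sk = skeletonize(tube_truth.vessel_mask, SP, compute_radii=False)
        assert count_branches(sk) == 0

    def test_y_tree_has_one(self, y_truth):
        sk = skeletonize(y_truth.vessel_mask, SP, compute_radii=False)
        assert count_branches(sk) == 1

    @pytest.mark.parametrize("seed", [12, 13, 14])
    def test_tree_recovery_within_one(self, grid, seed):
        from paskin import VesselTreeSpec, generate_vessel_tree

        truth = generate_vessel_tree(
            VesselTreeSpec(n_trees=3, branching_prob=0.3, seed=seed), grid
        )
        sk = skeletonize(truth.vessel_mask, SP, compute_radii=False)
        assert abs(count_branches(sk) - truth.branch_count) <= 1

    def test_empty_skeleton(self):
        sk = skeletonize(np.zeros((5, 5, 5), bool), SP, compute_radii=False)
        assert count_branches(sk) == 0


class TestAnalysisDepth:
    def test_support_defines_depth(self):
        mask = np.zeros((50, 8, 8), bool)
        mask[0:30] = True
        assert determine_analysis_depth(mask) == 30

    def test_override_wins(self):
        mask = np.zeros((50, 8, 8), bool)
        mask[0:30] = True
        assert determine_analysis_depth(mask, override=48) == 48

    def test_empty_mask_refused(self):
        with pytest.raises(ValueError, match="empty"):
            determine_analysis_depth(np.zeros((10, 4, 4), bool))

    def test_phantom_depth_recovered_within_four_slices(self, grid, spectra):
        """Vessels down to 1.8 mm on a 30 µm grid → D within ±4 of the support."""
        from paskin import VesselTreeSpec, generate_vessel_tree, synthesize_pa_volumes
        from paskin.phantom import PhantomTruth
        from paskin.segmentation import segment_slices
        from paskin.unmixing import vessel_channel

        bands = [(0.15, 0.6), (0.7, 1.2), (1.35, 1.68)]
        mask = np.zeros(grid.shape, bool)
        for i, band in enumerate(bands):
            part = generate_vessel_tree(
                VesselTreeSpec(
                    n_trees=4, depth_range_mm=band, branching_prob=0.2, seed=3 + 100 * i
                ),
                grid,
            )
            mask |= part.vessel_mask
        truth = PhantomTruth(
            grid=grid,
            vessel_mask=mask,
            c_hbo2=np.where(mask, 0.7, 0.0),
            c_hb=np.where(mask, 0.3, 0.0),
        )
        scan = synthesize_pa_volumes(truth, spectra, noise_sd=0.0)
        seg = segment_slices(vessel_channel(scan), grid.spacing_um)
        support = int(np.argwhere(mask)[:, 0].max()) + 1
        assert support >= 56  # the phantom really does reach ~1.8 mm
        assert abs(determine_analysis_depth(seg.mask) - support) <= 4


class TestRotationInvariance:
    def test_volume_and_branches_exact_under_rotation(self, tree_truth):
        mask = tree_truth.vessel_mask
        rot = np.rot90(mask, k=1, axes=(1, 2))  # 90° about the depth axis
        assert structure_volume(rot) == structure_volume(mask)
        sk = skeletonize(mask, SP, compute_radii=False)
        sk_r = skeletonize(np.ascontiguousarray(rot), SP, compute_radii=False)
        assert count_branches(sk_r) == count_branches(sk)

    def test_thickness_drift_under_rotation(self, grid):
        mask = digital_cylinder(grid, 4.0, axis="x", length_vox=70)
        rot = np.ascontiguousarray(np.rot90(mask, k=1, axes=(1, 2)))
        t1 = mean_thickness(skeletonize(mask, SP))
        t2 = mean_thickness(skeletonize(rot, SP))
        assert abs(t1 - t2) / t1 <= 0.05


class TestSO2Layers:
    def _partition(self):
        return partition_layers(60)

    def test_uniform_so2_recovered(self, grid):
        so2 = np.full(grid.shape, 0.7)
        valid = np.ones(grid.shape, bool)
        mask = np.zeros(grid.shape, bool)
        mask[5:35] = True
        m = SO2Map(so2=so2, valid=valid, wavelengths_used=(575.0, 586.0))
        out = mean_so2_per_layer(m, mask, self._partition())
        assert out[1] == pytest.approx(0.7, abs=1e-6)
        assert out[2] == pytest.approx(0.7, abs=1e-6)

    def test_layer_graded_phantom(self, grid, spectra):
        """Layer-1 vessels at 0.9, layer-2 at 0.6 → (0.9, 0.6) ± 0.01."""
        from paskin import compute_so2, synthesize_pa_volumes
        from paskin.phantom import straight_tube_truth

        t1 = straight_tube_truth(grid, radius_um=120.0, depth_um=300.0, so2=0.9)
        t2 = straight_tube_truth(grid, radius_um=120.0, depth_um=900.0, so2=0.6, axis="y")
        truth = t1
        truth.vessel_mask |= t2.vessel_mask
        for f in ("c_hbo2", "c_hb", "per_voxel_so2"):
            arr = getattr(truth, f)
            arr[t2.vessel_mask] = getattr(t2, f)[t2.vessel_mask]
        scan = synthesize_pa_volumes(truth, spectra, noise_sd=0.0)
        m = compute_so2(scan, spectra)
        out = mean_so2_per_layer(m, truth.vessel_mask, self._partition())
        assert out[1] == pytest.approx(0.9, abs=0.01)
        assert out[2] == pytest.approx(0.6, abs=0.01)

    def test_all_invalid_is_missing(self, grid):
        m = SO2Map(
            so2=np.full(grid.shape, np.nan),
            valid=np.zeros(grid.shape, bool),
            wavelengths_used=(575.0, 586.0),
        )
        out = mean_so2_per_layer(m, np.ones(grid.shape, bool), self._partition())
        assert out[1] is None and out[2] is None

    def test_shape_mismatch_refused(self, grid):
        m = SO2Map(
            so2=np.zeros((4, 4, 4)), valid=np.ones((4, 4, 4), bool), wavelengths_used=(575.0, 586.0)
        )
        with pytest.raises(ValueError, match="shape"):
            mean_so2_per_layer(m, np.ones(grid.shape, bool), LayerPartition(3, (0, 1, 2, 3)))
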