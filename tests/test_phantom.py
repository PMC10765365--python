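"""Generator ground truth: rasterization, bifurcation bookkeeping, forward model."""

import networkx as nx
import numpy as np
import pytest

from paskin import (
    ChromophoreSpectra,
    PhantomTruth,
    TorusParams,
    VesselTreeSpec,
    VoxelGrid,
    digital_cylinder,
    generate_melanin_layer,
    generate_vessel_tree,
    synthesize_pa_volumes,
)
from paskin.phantom import add_melanin_to_truth, straight_tube_truth


def polyline_graph_bifurcations(centerlines) -> int:
    """Independent oracle: degree-≥3 nodes of the polyline adjacency graph."""
    g = nx.Graph()
    for poly in centerlines:
        pts = [tuple(np.round(p[:3], 3)) for p in poly]
        g.add_edges_from(zip(pts[:-1], pts[1:]))
    return sum(1 for _, d in g.degree() if d >= 3)


class TestVesselTrees:
    def test_straight_tube_is_cylinder_without_bifurcations(self, grid, tube_truth):
        assert tube_truth.branch_count == 0
        # flat-ended digital cylinder: voxel count close to pi R^2 L
        r_vox = 120.0 / 30.0
        pts = tube_truth.centerlines[0]
        length_vox = np.linalg.norm(pts[-1, :3] - pts[0, :3]) / 30.0
        expected = np.pi * r_vox**2 * length_vox
        assert abs(tube_truth.vessel_volume_voxels - expected) / expected < 0.1

    @pytest.mark.parametrize("radius_vox", [3.0, 4.0, 6.0])
    def test_rasterization_consistency(self, grid, radius_vox):
        """|voxel count − πR²L| ≤ 10% for axis-aligned cylinders, R ≥ 3, L ≥ 50."""
        length = 100
        mask = digital_cylinder(grid, radius_vox, axis="x", length_vox=length)
        expected = np.pi * radius_vox**2 * length
        assert abs(mask.sum() - expected) / expected <= 0.1

    def test_y_bifurcation_counts_one(self, y_truth):
        assert y_truth.branch_count == 1
        assert polyline_graph_bifurcations(y_truth.centerlines) == 1

    @pytest.mark.parametrize("seed", [0, 3, 7, 21])
    def test_branch_count_matches_graph_oracle(self, grid, seed):
        """Recorded bifurcations equal the polyline-graph degree count."""
        truth = generate_vessel_tree(
            VesselTreeSpec(n_trees=3, branching_prob=0.3, seed=seed), grid
        )
        assert truth.branch_count == polyline_graph_bifurcations(truth.centerlines)

    def test_volume_bookkeeping_is_popcount(self, tree_truth):
        assert tree_truth.vessel_volume_voxels == int(tree_truth.vessel_mask.sum())

    def test_so2_consistent_with_concentrations(self, tree_truth):
        total = tree_truth.c_hbo2 + tree_truth.c_hb
        sel = total > 0
        assert np.allclose(
            tree_truth.c_hbo2[sel] / total[sel], tree_truth.per_voxel_so2[sel]
        )
        # SO2 defined exactly on the vessel mask
        assert np.array_equal(sel, tree_truth.vessel_mask)

    def test_unresolvable_radius_refused(self, grid):
        spec = VesselTreeSpec(radius_range_um=(20.0, 80.0))  # 0.67 voxels
        with pytest.raises(ValueError, match="unresolvable"):
            generate_vessel_tree(spec, grid)

    def test_seed_determinism(self, grid):
        spec = VesselTreeSpec(n_trees=3, branching_prob=0.3, seed=5)
        a = generate_vessel_tree(spec, grid)
        b = generate_vessel_tree(spec, grid)
        assert np.array_equal(a.vessel_mask, b.vessel_mask)
        assert a.branch_count_per_tree == b.branch_count_per_tree
        for pa, pb in zip(a.centerlines, b.centerlines):
            assert np.array_equal(pa, pb)


class TestForwardModel:
    def test_zero_concentrations_give_zero_volumes(self, grid, spectra):
        truth = PhantomTruth(grid=grid)
        scan = synthesize_pa_volumes(truth, spectra, noise_sd=0.0)
        for wl in scan.wavelengths_nm:
            assert not scan.volume(wl).any()

    def test_pure_melanin_signals_only_where_melanin(self, grid, spectra):
        truth = PhantomTruth(grid=grid)
        truth.c_melanin[5, 10, 10] = 2.0
        scan = synthesize_pa_volumes(truth, spectra, noise_sd=0.0, attenuation_per_mm=0.0)
        vol = scan.volume(650.0)
        assert vol[5, 10, 10] == pytest.approx(2.0 * spectra.melanin(650.0))
        assert np.count_nonzero(vol) == 1
        assert np.count_nonzero(scan.volume(575.0)) == 1  # melanin absorbs there too

    def test_hand_summed_amplitudes(self, grid):
        """C_HbO2 = C_Hb = 1 with eps_hbo2=(2,3), eps_hb=(4,1) → amplitudes (6, 4)."""
        sp = ChromophoreSpectra(
            wavelengths_nm=(575.0, 586.0), eps_hbo2=(2.0, 3.0), eps_hb=(4.0, 1.0)
        )
        truth = PhantomTruth(grid=grid)
        truth.c_hbo2[3, 4, 5] = 1.0
        truth.c_hb[3, 4, 5] = 1.0
        scan = synthesize_pa_volumes(
            truth, sp, wavelengths_nm=(575.0, 586.0), noise_sd=0.0, attenuation_per_mm=0.0
        )
        assert scan.volume(575.0)[3, 4, 5] == pytest.approx(6.0)
        assert scan.volume(586.0)[3, 4, 5] == pytest.approx(4.0)

    def test_linearity_in_concentrations(self, grid, spectra, tree_truth):
        one = synthesize_pa_volumes(tree_truth, spectra, noise_sd=0.0)
        doubled = PhantomTruth(
            grid=grid,
            vessel_mask=tree_truth.vessel_mask,
            c_hbo2=2 * tree_truth.c_hbo2,
            c_hb=2 * tree_truth.c_hb,
            c_melanin=2 * tree_truth.c_melanin,
            per_voxel_so2=tree_truth.per_voxel_so2,
        )
        two = synthesize_pa_volumes(doubled, spectra, noise_sd=0.0)
        for wl in one.wavelengths_nm:
            assert np.allclose(two.volume(wl), 2 * one.volume(wl))

    def test_missing_wavelength_in_spectra_errors(self, grid, spectra, tree_truth):
        with pytest.raises(KeyError):
            synthesize_pa_volumes(tree_truth, spectra, wavelengths_nm=(700.0,))

    def test_noise_is_seeded(self, spectra, tree_truth):
        a = synthesize_pa_volumes(tree_truth, spectra, noise_sd=0.05, seed=3)
        b = synthesize_pa_volumes(tree_truth, spectra, noise_sd=0.05, seed=3)
        c = synthesize_pa_volumes(tree_truth, spectra, noise_sd=0.05, seed=4)
        assert np.array_equal(a.volume(575.0), b.volume(575.0))
        assert not np.array_equal(a.volume(575.0), c.volume(575.0))


class TestMelaninLayer:
    def test_no_tori_empty_mask(self, grid):
        mask = generate_melanin_layer(grid, TorusParams(n_tori=0), seed=0)
        assert not mask.any()

    def test_single_torus_matches_inequality_scan(self, grid):
        """Mask equals a brute-force scan of the torus inequality over the grid."""
        params = TorusParams(n_tori=1, inner_radius_um=120.0, outer_radius_um=260.0)
        mask = generate_melanin_layer(grid, params, seed=4)
        # brute-force oracle: only one torus, recover its centre from the mask
        zc, yc, xc = grid.voxel_centers_um()
        pts = np.argwhere(mask)
        # ring centre: mean of the annulus is its centre by symmetry
        cz = (pts[:, 0].mean() + 0.5) * 30.0
        cyx = (pts[:, 1:].mean(axis=0) + 0.5) * 30.0
        R, r = params.major_radius_um, params.minor_radius_um
        rho = np.sqrt((yc - cyx[0]) ** 2 + (xc - cyx[1]) ** 2)
        lo, hi = params.depth_band_um
        oracle = (((rho - R) ** 2 + (zc - cz) ** 2) <= r**2) & (zc >= lo) & (zc < hi)
        # centre estimation is approximate: allow a small symmetric difference
        assert np.count_nonzero(mask ^ oracle) <= 0.1 * np.count_nonzero(oracle)
        assert mask.sum() == pytest.approx(oracle.sum(), rel=0.1)

    def test_five_tori_are_five_components(self, grid):
        from scipy import ndimage

        mask = generate_melanin_layer(grid, TorusParams(n_tori=5), seed=9)
        _, n = ndimage.label(mask, structure=np.ones((3, 3, 3), int))
        assert n == 5

    def test_band_misconfiguration_errors(self, grid):
        with pytest.raises(ValueError, match="fit the depth band"):
            TorusParams(
                inner_radius_um=100.0, outer_radius_um=900.0, depth_band_um=(0.0, 300.0)
            ).validate(grid)
        with pytest.raises(ValueError, match="within the grid"):
            TorusParams(depth_band_um=(0.0, 99999.0)).validate(grid)

    def test_melanin_truth_attachment(self, grid):
        truth = straight_tube_truth(grid, radius_um=120.0)
        mask = generate_melanin_layer(grid, TorusParams(n_tori=2), seed=1)
        add_melanin_to_truth(truth, mask, concentration=1.5)
        assert truth.melanin_volume_voxels == int(mask.sum())
        assert np.all(truth.c_melanin[mask] == 1.5)
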