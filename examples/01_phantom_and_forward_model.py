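"""Build a vessel phantom and synthesize its multi-wavelength scan.

Generates a small branching vessel network with known ground truth, runs the
absorption-proportional forward model at 575/586/650 nm, and prints the truth
bookkeeping that later stages are validated against.
"""

import numpy as np

from paskin import (
    VesselTreeSpec,
    VoxelGrid,
    default_phantom_spectra,
    generate_vessel_tree,
    synthesize_pa_volumes,
)

grid = VoxelGrid(shape=(64, 128, 128), spacing_um=(30.0, 30.0, 30.0))
spec = VesselTreeSpec(n_trees=4, branching_prob=0.3, seed=12)
truth = generate_vessel_tree(spec, grid)

print(f"grid: {grid.shape} voxels at {grid.spacing_um} um")
print(f"vessel volume : {truth.vessel_volume_voxels} voxels")
print(f"bifurcations  : {truth.branch_count} (per tree: {truth.branch_count_per_tree})")
print(f"centerlines   : {len(truth.centerlines)} polylines")

scan = synthesize_pa_volumes(
    truth, default_phantom_spectra(), noise_sd=0.05, attenuation_per_mm=0.4, seed=1
)
for wl in scan.wavelengths_nm:
    v = scan.volume(wl)
    print(f"{wl:.0f} nm amplitude: max {v.max():.0f} A.U., mean in vessels "
          f"{v[truth.vessel_mask].mean():.0f} A.U.")
# The 575 nm channel is hemoglobin-dominated; 650 nm would carry melanin if
# the phantom had any. Amplitudes are arbitrary units, decaying with depth.
print("per-voxel SO2 range in vessels:",
      np.round([truth.per_voxel_so2[truth.vessel_mask].min(),
                truth.per_voxel_so2[truth.vessel_mask].max()], 3))
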