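import numpy as np
import pytest

from paskin import (
    VesselTreeSpec,
    VoxelGrid,
    generate_vessel_tree,
    synthesize_pa_volumes,
    toy_spectra,
)
from paskin.phantom import straight_tube_truth, y_tree_truth


@pytest.fixture(scope="session")
def grid():
    """Default desk-scale isotropic 30 µm grid."""
    return VoxelGrid(shape=(64, 128, 128), spacing_um=(30.0, 30.0, 30.0))


@pytest.fixture(scope="session")
def small_grid():
    return VoxelGrid(shape=(40, 64, 64), spacing_um=(30.0, 30.0, 30.0))


@pytest.fixture(scope="session")
def spectra():
    return toy_spectra()


@pytest.fixture(scope="session")
def tube_truth(grid):
    """Straight flat-ended tube, radius 4 voxels, along x."""
    return straight_tube_truth(grid, radius_um=120.0, so2=0.8)


@pytest.fixture(scope="session")
def y_truth(grid):
    return y_tree_truth(grid)


@pytest.fixture(scope="session")
def tree_truth(grid):
    """Random branching trees with recorded ground truth."""
    return generate_vessel_tree(
        VesselTreeSpec(n_trees=4, branching_prob=0.3, seed=12), grid
    )


@pytest.fixture(scope="session")
def tree_scan(tree_truth, spectra):
    """Noise-free multi-wavelength scan of the tree phantom (toy spectra)."""
    return synthesize_pa_volumes(
        tree_truth, spectra, wavelengths_nm=(575.0, 586.0, 650.0), noise_sd=0.0
    )


def dice(a: np.ndarray, b: np.ndarray) -> float:
    inter = np.count_nonzero(a & b)
    return 2.0 * inter / (np.count_nonzero(a) + np.count_nonzero(b))
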