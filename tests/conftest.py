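import numpy as np
import pytest

from pocketscreen import build_grid, detect_pockets
from pocketscreen.fixtures import make_pocket_structure

DETECT_MIN_VOXELS = 24  # ~3 A^3 at 0.5 A spacing; suppresses surface noise


@pytest.fixture(scope="session")
def open_cavity():
    """Slab with an open radius-5 cavity, detected at 0.5 A spacing."""
    structure, manifest = make_pocket_structure(5.0, sealed=False, seed=7)
    grid = build_grid(structure, spacing=0.5)
    pockets = detect_pockets(grid, min_voxels=DETECT_MIN_VOXELS)
    return structure, manifest, grid, pockets


@pytest.fixture(scope="session")
def sealed_cavity():
    structure, manifest = make_pocket_structure(5.0, sealed=True, seed=7)
    grid = build_grid(structure, spacing=0.5)
    pockets = detect_pockets(grid, min_voxels=DETECT_MIN_VOXELS)
    return structure, manifest, grid, pockets


@pytest.fixture(scope="session")
def small_cavity():
    """A second, smaller pocket (radius 4) for cross-pocket comparisons."""
    structure, manifest = make_pocket_structure(4.0, sealed=False, seed=11)
    grid = build_grid(structure, spacing=0.5)
    pockets = detect_pockets(grid, min_voxels=DETECT_MIN_VOXELS)
    return structure, manifest, grid, pockets


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
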