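import numpy as np
import pytest
from hypothesis import settings

import anisocell as ac

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_spec():
    """Three-layer organ, coarse voxels: fast to rasterize."""
    return ac.OrganSpec(
        organ_radius=18.0,
        segment_length=24.0,
        n_layers=3,
        per_layer_cell_dims=[(8, 4, 5), (8, 5, 6), (8, 5, 6)],
        voxel_spacing=(1.0, 1.0, 1.0),
    )


@pytest.fixture(scope="session")
def small_tissue(small_spec):
    return ac.build_tissue(small_spec, seed=7)


@pytest.fixture(scope="session")
def fine_tissue():
    """Straight organ rasterized at 0.5 µm: the measurement benchmark."""
    spec = ac.OrganSpec(
        organ_radius=18.0,
        segment_length=24.0,
        n_layers=3,
        per_layer_cell_dims=[(8, 4, 5), (8, 5, 6), (8, 5, 6)],
        voxel_spacing=(0.5, 0.5, 0.5),
    )
    return ac.build_tissue(spec, seed=3)


@pytest.fixture(scope="session")
def grid_volume():
    """27 cuboidal cells in a ~64³ stack, all interior to the faces."""
    return ac.build_grid_labels(n_cells=(3, 3, 3), cell_voxels=(18, 18, 18), margin=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
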