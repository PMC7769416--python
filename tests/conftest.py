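import numpy as np
import pytest

import scatterrisk as sr
from scatterrisk.phantom import OrganSpec, PhantomSpec


@pytest.fixture(scope="session")
def torso_phantom():
    """The shipped simplified female torso, built once per session."""
    return sr.build_synthetic_phantom(sr.female_torso_spec())


@pytest.fixture(scope="session")
def water_slab():
    """Homogeneous water slab, 100 x 360 x 100 mm at 4 mm voxels."""
    spec = PhantomSpec(
        shape=(25, 90, 25),
        spacing_mm=(4.0, 4.0, 4.0),
        organs=[OrganSpec(1, "water", "box", (50, 180, 50), (50, 180, 50), "water")],
        name="water_slab",
    )
    return sr.build_synthetic_phantom(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260928)


def make_dose_grid(values, spacing=(4.0, 4.0, 4.0), rel_unc=None):
    """Helper: wrap an array (and optional relative uncertainty) as a DoseGrid."""
    values = np.asarray(values, dtype=float)
    grid = sr.VoxelGrid(values=values, spacing=spacing, units="Gy")
    unc = np.zeros_like(values) if rel_unc is None else np.asarray(rel_unc, float)
    return sr.DoseGrid(
        dose=grid, rel_uncertainty=sr.VoxelGrid(values=unc, spacing=spacing)
    )
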