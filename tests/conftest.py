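import numpy as np
import pytest

from laminaprof import synth


@pytest.fixture(scope="session")
def shell_phantom():
    """Small spherical-shell phantom shared across tests."""
    spec = synth.PhantomSpec(
        voxel_size_mm=(0.8, 0.8, 0.8), inner_radius_mm=8.0, outer_radius_mm=11.0
    )
    return spec, synth.make_phantom(spec)


@pytest.fixture(scope="session")
def slab_phantom():
    """Slab phantom: 3 mm ribbon, 0.3 mm voxels -> 10 GM rows."""
    spec = synth.PhantomSpec(
        geometry="slab",
        thickness_mm=3.0,
        voxel_size_mm=(0.3, 0.3, 0.3),
        extent_mm=(6.0, 6.0),
    )
    return spec, synth.make_phantom(spec)


@pytest.fixture(scope="session")
def noiseless_protocol():
    return synth.default_protocol(snr=np.inf)


@pytest.fixture(scope="session")
def default_cohort():
    spec = synth.CohortSpec(seed=11)
    return spec, synth.make_cohort(spec)
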