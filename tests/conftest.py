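import numpy as np
import pytest

import kurtosig as kg


@pytest.fixture(scope="session")
def scheme():
    """The 6-shell, 30-direction protocol scheme (151 volumes)."""
    return kg.default_scheme()


@pytest.fixture(scope="session")
def small_spec():
    """A coarse phantom (same world geometry, 4x4x10 mm voxels) for fast tests."""
    return kg.PhantomSpec(
        grid_shape=(32, 32, 12),
        voxel_size=(4.0, 4.0, 10.0),
        anat_voxel_size=(2.0, 2.0, 6.0),
        seed=7,
    )


@pytest.fixture(scope="session")
def small_truth(small_spec):
    return kg.build_phantom(small_spec)


@pytest.fixture(scope="session")
def small_dwi(small_truth, scheme):
    return kg.simulate_dwi(small_truth, scheme, snr=np.inf)


@pytest.fixture(scope="session")
def small_fit(small_dwi, small_truth):
    """Noiseless, unsmoothed fit of the small phantom."""
    return kg.DiffusionKurtosisModel(small_dwi, small_truth.brain_mask, sigma=0).fit()


@pytest.fixture(scope="session")
def truth_maps(small_truth):
    """Ground-truth MD/MK as ParametricMaps (no fitting involved)."""
    return (
        kg.ParametricMap(small_truth.md_truth, "MD", small_truth.grid),
        kg.ParametricMap(small_truth.mk_truth, "MK", small_truth.grid),
    )
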