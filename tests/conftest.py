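import numpy as np
import pytest

from peraf import BoldImage, SimulationConfig


@pytest.fixture
def tiny_sim_config():
    """Desk-scale simulation: 10^3 grid, 40 timepoints, one planted sphere."""
    return SimulationConfig(
        grid_shape=(10, 10, 10), n_timepoints=40, n_per_group=3,
        effect_rois=(((5, 5, 5), 2.0),), spatial_fwhm_mm=0.0,
        subject_amp_cv=0.0, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


def make_bold(data, tr_s=2.0, voxel_mm=3.0):
    affine = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    return BoldImage(data=np.asarray(data, float), affine=affine, tr_s=tr_s)
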