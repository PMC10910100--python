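import numpy as np
import pytest

from dimani import (
    DWIDataset,
    GradientTable,
    build_phantom,
    preset_thalamus,
)


def make_dataset(signal, bvals, bvecs=None, affine=None):
    """Small helper assembling a DWIDataset from raw arrays."""
    signal = np.asarray(signal, dtype=float)
    bvals = np.asarray(bvals, dtype=float)
    if bvecs is None:
        rng = np.random.default_rng(0)
        bvecs = rng.normal(size=(len(bvals), 3))
        bvecs /= np.linalg.norm(bvecs, axis=1, keepdims=True)
        bvecs[bvals == 0] = 0.0
    if affine is None:
        affine = np.eye(4)
    return DWIDataset(signal, affine, GradientTable(bvals, bvecs))


def voxel_series_dataset(series):
    """A 1x1x1 dataset whose single voxel holds the given weighted series
    (plus one b0 volume set to an arbitrary baseline)."""
    series = np.asarray(series, dtype=float)
    signal = np.concatenate([[123.0], series]).reshape(1, 1, 1, -1)
    bvals = np.concatenate([[0.0], np.full(len(series), 1500.0)])
    return make_dataset(signal, bvals)


@pytest.fixture(scope="session")
def thalamus_noisefree():
    """Noise-free preset thalamus build (48 directions, b=1500, 4 b0s)."""
    return build_phantom(preset_thalamus(seed=7, noise_sigma=0.0))


@pytest.fixture(scope="session")
def thalamus_noisy():
    """Preset thalamus at the default noise level (sigma = 2% of S0)."""
    return build_phantom(preset_thalamus(seed=7))
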