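import numpy as np
import pytest

from fractalct.preprocess import CTVolume, SegmentationMask, save_mask, save_volume
from fractalct.synthetic import SimulationConfig, make_phantom, simulate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def menger2():
    return make_phantom("menger", 2)


@pytest.fixture
def cube64():
    return make_phantom("cube", 64)


@pytest.fixture
def small_cohort():
    """Deterministic 400-patient simulated cohort shared across tests."""
    return simulate_cohort(SimulationConfig(n_patients=400, seed=42))


@pytest.fixture
def nifti_pair(tmp_path):
    """Write a volume/mask NIfTI pair; returns (vol_path, mask_path, vol, mask)."""

    def _write(data, mask_data, spacing=(1.0, 1.0, 1.0)):
        vol = CTVolume(data=np.asarray(data, dtype=float), spacing=spacing)
        mask = SegmentationMask(data=mask_data, spacing=spacing)
        vp, mp = tmp_path / "vol.nii", tmp_path / "mask.nii"
        save_volume(vol, vp)
        save_mask(mask, mp)
        return vp, mp, vol, mask

    return _write
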