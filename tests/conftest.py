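import numpy as np
import pytest

from cardioscar.synth.cmr import ScarRegion, SyntheticCMRSpec, generate_cmr
from cardioscar.synth.optical import SyntheticOpticalSpec, disk_mask, generate_optical


@pytest.fixture(scope="session")
def scar_phantom():
    """Noiseless LGE phantom with epi DS+HT and endo DS+HT sectors."""
    spec = SyntheticCMRSpec(
        scar_regions=[
            ScarRegion(0, 110, 0, 6, "epi", 3.6),
            ScarRegion(110, 180, 0, 6, "epi", 2.5),
            ScarRegion(0, 150, 0, 6, "endo", 3.6),
            ScarRegion(150, 190, 0, 6, "endo", 2.5),
        ],
        noise_sd=0.0,
        seed=7,
    )
    return generate_cmr(spec)


@pytest.fixture(scope="session")
def plane_wave():
    """Noiseless uniform plane wave, 50 cm/s, left-edge origin."""
    spec = SyntheticOpticalSpec(
        grid_shape=(48, 48),
        pixel_size=0.5,
        frame_interval=1.0,
        n_beats=3,
        hm_velocity_cm_s=50.0,
        noise_sd=0.0,
        seed=1,
    )
    return generate_optical(spec)


@pytest.fixture(scope="session")
def ht_patch_movie():
    """Noiseless movie with a slow, long-APD heterogeneous-tissue disk."""
    mask = disk_mask((64, 64), (31.5, 40.0), 13.0)
    spec = SyntheticOpticalSpec(
        grid_shape=(64, 64),
        pixel_size=0.5,
        frame_interval=1.0,
        n_beats=3,
        hm_velocity_cm_s=50.0,
        ht_mask=mask,
        ht_velocity_ratio=0.55,
        ht_apd_ratio=1.3,
        noise_sd=0.0,
        seed=3,
    )
    return generate_optical(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)
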