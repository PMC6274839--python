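import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import coilflex as cf

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture(scope="session")
def wlc_small():
    """Small worm-like-chain ensemble shared across geometry tests."""
    return cf.sample_wlc_ensemble(
        cf.WLCParams(lp_nm=80.0, n_frames=40, seed=7)
    )


@pytest.fixture(scope="session")
def backbone_ensemble(wlc_small):
    """Pseudo-atomic two-chain build with full backbone (N,H,CA,C,O)."""
    return cf.build_coiled_coil_ensemble(
        wlc_small, cf.CoiledCoilBuildParams(place_backbone="backbone")
    )


@pytest.fixture(scope="session")
def ca_ensemble(wlc_small):
    return cf.build_coiled_coil_ensemble(
        wlc_small, cf.CoiledCoilBuildParams(place_backbone="CA")
    )


def random_rotation(rng):
    from scipy.spatial.transform import Rotation

    q = rng.normal(size=4)
    return Rotation.from_quat(q / np.linalg.norm(q)).as_matrix()
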