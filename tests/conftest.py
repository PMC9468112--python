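import numpy as np
import pytest

import spinereg as sr


@pytest.fixture(scope="session")
def phantom():
    """Default 5-vertebra spine phantom (deterministic)."""
    volume, models = sr.make_phantom(seed=1)
    return volume, models


@pytest.fixture(scope="session")
def noise_free_case():
    """RAD-90 test case with all degradation switched off and no view-2
    angulation jitter: the true geometry equals the nominal one."""
    cfg = sr.CaseConfig(
        angulation_pair=(-45.0, 45.0),
        angulation_jitter_deg=0.0,
        noise=sr.NoiseConfig(gain=0.0, gaussian_sd=0.0, intensity_scale=1.0, intensity_offset=0.0),
    )
    return sr.make_test_case(cfg, seed=7)


@pytest.fixture(scope="session")
def default_case():
    """RAD-90 case under the default noise/jitter study conditions."""
    cfg = sr.CaseConfig(angulation_pair=(-45.0, 45.0))
    return sr.make_test_case(cfg, seed=7)


@pytest.fixture(scope="session")
def sphere_volume():
    """Homogeneous (anti-aliased) sphere, r = 20 mm, mu = 0.02/mm."""
    shape = (96, 96, 96)
    spacing = np.ones(3)
    origin = -(np.array(shape) - 1) / 2.0
    ax = [origin[i] + np.arange(shape[i]) for i in range(3)]
    X, Y, Z = np.meshgrid(*ax, indexing="ij")
    d = np.sqrt(X**2 + Y**2 + Z**2) - 20.0
    vals = 0.02 * np.clip(0.5 - d, 0.0, 1.0)
    return sr.VolumeImage(vals, spacing, origin)


def random_pose(rng, t_scale=10.0, r_scale=30.0, center=None):
    if center is None:
        center = rng.uniform(-20, 20, 3)
    return sr.RigidPose(
        rng.uniform(-t_scale, t_scale, 3), rng.uniform(-r_scale, r_scale, 3), center
    )
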