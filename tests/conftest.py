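import numpy as np
import pytest

from oximap.calibrate import build_training_set, fit_matrix
from oximap.camera import default_camera_model
from oximap.mcs import McsConfig, build_albedo_lut


@pytest.fixture(scope="session")
def camera():
    return default_camera_model()


@pytest.fixture(scope="session")
def fast_cfg():
    """Modest photon budget shared by the unit tests."""
    return McsConfig(n_photons=20_000, seed=11)


@pytest.fixture(scope="session")
def lut(fast_cfg):
    return build_albedo_lut(n_knots=21, cfg=fast_cfg)


@pytest.fixture(scope="session")
def training(fast_cfg, camera, lut):
    return build_training_set(cfg=fast_cfg, model=camera, lut=lut)


@pytest.fixture(scope="session")
def matrix(training):
    return fit_matrix(training)


def brute_force_reflectance(mu_a, mu_s_prime, n_photons, seed, thickness_mfp=np.inf):
    """Independent unweighted oracle: at each interaction the photon is absorbed
    with probability mu_a/(mu_a+mu_s') or scattered isotropically; an escape
    through the top surface counts one full photon. Scalar-loop on purpose."""
    rng = np.random.default_rng(seed)
    p_abs = mu_a / (mu_a + mu_s_prime)
    escaped = 0
    for _ in range(n_photons):
        z, uz = 0.0, 1.0
        while True:
            step = rng.exponential()
            z_new = z + uz * step
            if z_new < 0.0:
                escaped += 1
                break
            if z_new > thickness_mfp:
                break
            if rng.random() < p_abs:
                break
            z = z_new
            uz = 2.0 * rng.random() - 1.0
    refl = escaped / n_photons
    se = np.sqrt(refl * (1.0 - refl) / n_photons)
    return refl, se
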