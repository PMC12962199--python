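import numpy as np
import pytest

import lungshim as ls


@pytest.fixture(scope="session")
def default_phantom():
    """Default 128x128 phantom with its geometry (shared, read-only)."""
    truth, geometry = ls.make_phantom(ls.PhantomParams(), seed=0)
    return truth, geometry


@pytest.fixture(scope="session")
def noiseless_series(default_phantom):
    """Noiseless, motion-free single-repetition acquisition."""
    truth, geometry = default_phantom
    return ls.simulate_echo_series(
        truth, geometry, te1=570, delta_t=100, n_echoes=4, n_reps=1,
        snr=np.inf, motion_amplitude=0, seed=1,
    )


@pytest.fixture(scope="session")
def noiseless_fieldmap(noiseless_series):
    return ls.fieldmap_from_series(noiseless_series)


def uniform_truth(shape=(16, 16), m0=1.0, t2star_us=640.0, nu_hz=70.0, phi0=0.2):
    """Tiny spatially uniform truth for closed-form forward-model checks."""
    ones = np.ones(shape)
    mask = np.zeros(shape, dtype=bool)
    mask[4:12, 4:12] = True
    return ls.PhantomTruth(
        m0_map=m0 * ones,
        t2star_map=t2star_us * ones,
        nu_map=nu_hz * ones,
        phi0_map=phi0 * ones,
        lung_mask=mask,
        body_mask=np.ones(shape, dtype=bool),
    )


def uniform_geometry(shape=(16, 16)):
    return ls.Geometry2D(matrix=shape, fov_mm=(float(shape[0]), float(shape[1])))
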