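import numpy as np
import pytest

import asymei as a

# outer sampling points at +/-15 um and 50% of the peak => Gaussian sigma
OUTER_OFFSET = 15.0
WIDTH = OUTER_OFFSET / np.sqrt(2.0 * np.log(2.0))


@pytest.fixture
def ic():
    return a.make_ic(1.0, WIDTH, 0.0, 0.0)


@pytest.fixture
def scheme(ic):
    return a.place_half_max_scheme(ic, inner_fraction=1.0 / 3.0)


@pytest.fixture
def geom():
    return a.SystemGeometry(z_m1=1.5, z_m2=1.95, z_det=2.0, detector_pitch=100.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def forward_four_point(scheme, transmission, dphi, sigma2):
    """Reference second-order forward model, hand-coded for oracle use.

    Broadcasts the three parameter arrays against the four scheme points on
    a trailing axis, returning shape ``(..., 4)``.
    """
    R, Rd, Rdd = scheme.R, scheme.Rdot, scheme.Rddot
    transmission = np.asarray(transmission, dtype=float)[..., None]
    dphi = np.asarray(dphi, dtype=float)[..., None]
    sigma2 = np.asarray(sigma2, dtype=float)[..., None]
    return transmission * (R + Rd * dphi + 0.5 * Rdd * (dphi**2 + sigma2))
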