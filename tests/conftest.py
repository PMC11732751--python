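import numpy as np
import pytest

from equaflux import eos
from equaflux.hydrography import Profile


def sigma_to_ct(sigma, sa=35.0):
    """Invert the package equation of state: conservative temperature giving
    the requested sigma_Theta at salinity ``sa`` (vectorised)."""
    sigma = np.asarray(sigma, float)
    c = (eos._SIGMA_REF - sigma) / eos.RHO0 + eos._BETA * (sa - eos._S_REF)
    dt = (-eos._A0 + np.sqrt(eos._A0**2 + 2.0 * eos._A1 * c)) / eos._A1
    return eos._T_REF + dt


def profile_from_sigma(depth, sigma, sa=35.0, **kw):
    """Build a Profile whose sigma_Theta equals ``sigma`` exactly."""
    depth = np.asarray(depth, float)
    ct = sigma_to_ct(sigma, sa)
    return Profile(depth=depth, ct=ct, sa=np.full_like(depth, sa), **kw)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
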