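import numpy as np
import pytest

from spinelab import flim, synthetic


@pytest.fixture(scope="session")
def mixture_histogram():
    """A well-populated simulated histogram with known parameters."""
    params = flim.DecayParams(f0=1.0, p_ad=0.3, tau_d=2.6, tau_ad=1.3, tau_g=0.2, t0=1.0)
    hist = synthetic.simulate_photon_histogram(params, n_photons=300_000, seed=42)
    return params, hist


@pytest.fixture(scope="session")
def donor_histogram():
    """A pure free-donor (no FRET) histogram."""
    params = flim.DecayParams(f0=1.0, p_ad=0.0, tau_d=2.6, tau_ad=1.3, tau_g=0.2, t0=1.0)
    hist = synthetic.simulate_photon_histogram(params, n_photons=300_000, seed=43)
    return params, hist


@pytest.fixture
def rng():
    return np.random.default_rng(7)
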