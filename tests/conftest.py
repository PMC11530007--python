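import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_library():
    from polaridar import synthdata

    return synthdata.make_species_library(5, seed=11)


@pytest.fixture(scope="session")
def small_observations(small_library):
    """120 field-like observations with truth, transit-filtered."""
    from polaridar import synthdata

    by_id = {p.species_id: p for p in small_library}
    truths = synthdata.sample_events(small_library, 160, seed=12)
    obs = [
        synthdata.synth_waveform(by_id[t.species_id], t, noise_sd=0.05, seed=500 + i)
        for i, t in enumerate(truths)
    ]
    return [o for o in obs if o.transit_ms > 40.0]


@pytest.fixture(scope="session")
def spectrum_pairs(small_observations):
    from polaridar import spectra

    return [spectra.spectrum_pair(o.waveform_co, o.waveform_de) for o in small_observations]


def random_spectrum_pair(rng):
    from polaridar import spectra

    return spectra.SpectrumPair(
        p_co=rng.uniform(0.0, 1.0, spectra.N_BINS),
        p_de=rng.uniform(0.0, 1.0, spectra.N_BINS),
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240614)
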