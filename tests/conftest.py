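import numpy as np
import pytest

from fidashift.physics import (
    CapillarySetup,
    Species,
    capdis_protocol,
    capmix_protocol,
    noise_sd_for_snr,
    simulate_taylorgram,
)


@pytest.fixture(scope="session")
def capillary() -> CapillarySetup:
    return CapillarySetup()


@pytest.fixture(scope="session")
def capmix():
    return capmix_protocol()


@pytest.fixture(scope="session")
def capdis():
    return capdis_protocol()


@pytest.fixture
def clean_trace(capillary, capmix):
    """Noise-free single-species (3.5 nm) CapMix Taylorgram."""
    return simulate_taylorgram([Species(3.5, 1.0)], capmix, capillary)


@pytest.fixture
def noisy_trace(capillary, capmix):
    """3.5 nm CapMix trace at S/N 100 with baseline drift."""
    mix = [Species(3.5, 1.0)]
    noise = noise_sd_for_snr(mix, capmix, capillary, snr=100.0)
    return simulate_taylorgram(mix, capmix, capillary, baseline=(1.0, 0.002),
                               noise_sd=noise, seed=1234)
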