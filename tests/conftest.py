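import pytest

from bpiso import IsotopeValue, SyntheticConfig


@pytest.fixture
def noiseless_config() -> SyntheticConfig:
    """Instrument distortion present but zero noise everywhere."""
    return SyntheticConfig(
        noise_base_sigma=0.0,
        noise_amplitude_coeff=0.0,
        growth_noise_sd=0.0,
    )


@pytest.fixture
def identity_config() -> SyntheticConfig:
    """A perfect instrument: no offset, no scale compression, no size
    effect, no noise, no hydrogenation dilution."""
    return SyntheticConfig(
        noise_base_sigma=0.0,
        noise_amplitude_coeff=0.0,
        growth_noise_sd=0.0,
        cal_offset=0.0,
        cal_scale=1.0,
        cal_size_coeff=0.0,
        n_added_h=0,
    )


def iso(value, sigma=0.0, n=1) -> IsotopeValue:
    return IsotopeValue(value, sigma, n)
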