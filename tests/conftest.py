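import pytest

from follimech import GeneratorConfig, TipGeometry


@pytest.fixture
def config() -> GeneratorConfig:
    """Noiseless acquisition at the nominal cantilever settings."""
    return GeneratorConfig(seed=123)


@pytest.fixture
def noisy_config() -> GeneratorConfig:
    """5% multiplicative deflection noise, the study's working noise level."""
    return GeneratorConfig(seed=123, noise_fraction_deflection=0.05)


@pytest.fixture
def geometry() -> TipGeometry:
    return TipGeometry()
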