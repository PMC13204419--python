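import pytest

from lightdose import (
    ChromophoreSpectra,
    OpticalProperties,
    ProbeGeometry,
    forearm_phantom,
)


@pytest.fixture
def skin_730() -> OpticalProperties:
    """Forearm-skin-like optics at 730 nm (literature reduced scattering)."""
    return OpticalProperties(mu_a=0.01, mu_s_prime=1.41, g=0.9)


@pytest.fixture
def probe() -> ProbeGeometry:
    """As-built probe layout: near 4.2 mm, far 20.1 mm."""
    return ProbeGeometry(4.2, 20.1)


@pytest.fixture
def spectra() -> ChromophoreSpectra:
    return ChromophoreSpectra.default_table()


@pytest.fixture
def quiet_phantom():
    """Noise-free default phantom (exact round trips)."""
    return forearm_phantom(seed=7, noise_rsd=0.0)
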