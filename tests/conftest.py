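import numpy as np
import pytest

from silkbls import ScatteringConfig, TIElasticTensor, fixtures


@pytest.fixture(scope="session")
def silkworm() -> TIElasticTensor:
    """Silkworm silk at 0% strain (four independent constants, C66 = C44)."""
    return fixtures()["silkworm_0"]


@pytest.fixture(scope="session")
def spider() -> TIElasticTensor:
    """Spider dragline silk at 0% strain (five independent constants)."""
    return fixtures()["spider_0"]


@pytest.fixture
def transmission_cfg() -> ScatteringConfig:
    return ScatteringConfig(wavelength_nm=532, theta_deg=90, n=1.54, geometry="transmission")


@pytest.fixture
def reflection_cfg() -> ScatteringConfig:
    return ScatteringConfig(wavelength_nm=532, theta_deg=120, n=1.54, geometry="reflection")


def random_valid_tensor(rng: np.random.Generator) -> TIElasticTensor:
    """A random positive-definite transversely isotropic tensor (shared helper)."""
    C33 = rng.uniform(5, 80)
    C11 = rng.uniform(2, 60)
    C44 = rng.uniform(0.2, 0.45 * min(C11, C33))
    C66 = rng.uniform(0.1, 0.95 * C11 / 2 + 0.05)
    scale = np.sqrt((C11 - C66) * C33)
    # sample on the conventional C13 + C44 > 0 branch (phase velocities only
    # determine (C13 + C44)^2)
    t = rng.uniform(max(-0.9, (-0.95 * C44) / scale), 0.9)
    C13 = t * scale
    rho = rng.uniform(800, 2000)
    return TIElasticTensor.from_constants(C11=C11, C33=C33, C44=C44, C13=C13, rho=rho, C66=C66)
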