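import numpy as np
import pytest

from thyromech import HyperelasticParams, PronyParams


@pytest.fixture(scope="session")
def yeoh_reference() -> HyperelasticParams:
    """Calibrated Yeoh coefficients of porcine thyroid parenchyma (MPa)."""
    return HyperelasticParams.yeoh(1.9e-3, -2.3e-3, 0.04)


@pytest.fixture(scope="session")
def prony_reference() -> PronyParams:
    """Four-term relaxation fit of porcine thyroid (MPa, s)."""
    return PronyParams(
        moduli=(0.91, 0.82, 0.76, 0.49),
        taus=(8.83, 88.68, 784.29, 2.89e3),
        equilibrium=0.51,
    )


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20260928)
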