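import numpy as np
import pytest

from neurocurve import (CovariateTable, build_contrast, split_design,
                        default_phantom_spec, generate_phantom)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_phantom():
    """8x8x8, L=60 phantom with the three default signal regions."""
    spec = default_phantom_spec(seed=7, shape=(8, 8, 8), L=60)
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def default_phantom():
    """The standard 16x16x16, L=80 phantom."""
    return generate_phantom(default_phantom_spec(seed=3))


@pytest.fixture
def phantom_split(small_phantom):
    """Design split selecting the disease index as sole predictor."""
    contrast = np.array([[0.0], [0.0], [1.0]])
    return split_design(small_phantom.covariates, build_contrast(contrast))


def make_table(rng, L=30, M=3):
    return CovariateTable(rng.normal(size=(L, M)),
                          [f"c{j}" for j in range(M)])
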