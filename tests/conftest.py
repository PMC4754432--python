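import numpy as np
import pytest

from gwasmix import ModelParams, SnpContext

# Parameter sets used throughout: a highly polygenic case-control phenotype
# and a much less polygenic quantitative trait (sd convention:
# pi1, sigma0, sigma_a, sigma_b).
SCZ_SIGMAS = (0.037, 1.014, 0.0057, 0.020)
PUTAMEN_SIGMAS = (0.0010, 1.002, 0.0033, 0.034)


@pytest.fixture(scope="session")
def scz_params() -> ModelParams:
    return ModelParams.from_sigmas(*SCZ_SIGMAS)


@pytest.fixture(scope="session")
def putamen_params() -> ModelParams:
    return ModelParams.from_sigmas(*PUTAMEN_SIGMAS)


@pytest.fixture(scope="session")
def ctx_nh_1e4() -> SnpContext:
    """Context with N*H = 1e4 (the scale used for frozen reference values)."""
    return SnpContext(n_eff=34000.0, het=1e4 / 34000.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20160215)
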