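import numpy as np
import pytest

from mutvortex.analytic_model import ModelParams, VortexModel, VortexResults
from mutvortex.genome_sim import GenomeArchitecture


@pytest.fixture(scope="session")
def default_params() -> ModelParams:
    """Reference parameterisation: Ud=2, Ud/Ub=1000, exp(0.001) beneficial,
    human non-synonymous gamma deleterious DFE, static environment."""
    return ModelParams.default()


@pytest.fixture(scope="session")
def fitted_default(default_params) -> VortexResults:
    """Solved tipping point for the reference parameters (shared: the fit
    costs a few seconds of quadrature)."""
    return VortexModel(default_params).fit()


@pytest.fixture(scope="session")
def fitted_env() -> VortexResults:
    """Tipping point with environmental deterioration -1.5e-5 per generation."""
    return VortexModel(ModelParams.default(delta_env=-1.5e-5)).fit()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_arch() -> GenomeArchitecture:
    """Toy genome for pure-Python path tests: 4 chromosomes x 10 blocks."""
    return GenomeArchitecture(n_chromosomes=4, blocks_per_chromosome=10)
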