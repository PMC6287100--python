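import numpy as np
import pytest
from hypothesis import settings

from netcgas import ScenarioSpec, simulate_dataset

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_dataset():
    """Complete-case dataset with one causal SNP, two covariates and nulls."""
    spec = ScenarioSpec(
        n=500, maf=0.3, b_direct=0.2, b_cov=(0.3, -0.2), b_med=(0.1, 0.0),
        residual_cor=((1.0, 0.4, 0.1), (0.4, 1.0, 0.2), (0.1, 0.2, 1.0)),
        network_shape="star", n_null_snps=5, seed=7,
    )
    return simulate_dataset(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_dosage_vector(rng, n, maf=0.3):
    return rng.binomial(2, maf, size=n).astype(float)
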