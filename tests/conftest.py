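import numpy as np
import pytest

from varhet.distributions import DistributionSpec, MixtureSpec, sample_mixture


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def bimodal_4sd():
    """Equal-weight Gaussian mixture with modes 4 SDs apart."""
    return MixtureSpec(
        [
            DistributionSpec("normal", {"mean": 0.0, "sd": 1.0}),
            DistributionSpec("normal", {"mean": 4.0, "sd": 1.0}),
        ],
        [0.5, 0.5],
    )


@pytest.fixture(scope="session")
def bimodal_sample(bimodal_4sd):
    """A strongly bimodal fixture sample (n=400) with true labels."""
    values, labels = sample_mixture(bimodal_4sd, 400, 7)
    return values, labels
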