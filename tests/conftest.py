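import pytest

from nanoscape import MixtureParams, StochasticModel


@pytest.fixture(scope="session")
def std_normal_mixture():
    return MixtureParams([1.0], [0.0], [1.0])


@pytest.fixture(scope="session")
def symmetric_bimodal():
    """Equal-weight components at -1 and +1, unit variances."""
    return MixtureParams([0.5, 0.5], [-1.0, 1.0], [1.0, 1.0])


@pytest.fixture(scope="session")
def ou_model():
    """Single-Gaussian model: the dynamics are an Ornstein-Uhlenbeck process."""
    return StochasticModel(MixtureParams([1.0], [1.5], [0.16]), noise=0.4)


@pytest.fixture(scope="session")
def trimodal_model():
    """Well-separated three-component landscape, decade-scaled."""
    mix = MixtureParams([0.3, 0.4, 0.3], [0.5, 1.6, 2.6], [0.04, 0.05, 0.04])
    return StochasticModel(mix, noise=0.3)
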