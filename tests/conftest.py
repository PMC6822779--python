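import numpy as np
import pytest

from confsig import DiscriminabilityPrior, methods_priors


@pytest.fixture(scope="session")
def nine_priors() -> list[DiscriminabilityPrior]:
    """The nine discriminability distributions of the main design."""
    return methods_priors()


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def brute_posterior(values, sigma_I, e_I, sigma_d=None, e_d=None):
    """Independent direct-summation posterior for discrete uniform priors.

    Plain-python Bayes rule over the support, sharing no code with the
    engine: unnormalised Gaussian kernels, explicit double loop over
    identity and support.
    """
    import math

    num = 0.0
    den = 0.0
    for ident in (1, -1):
        for d in values:
            term = math.exp(-((e_I - d * ident) ** 2) / (2.0 * sigma_I**2))
            if sigma_d is not None:
                term *= math.exp(-((e_d - d) ** 2) / (2.0 * sigma_d**2))
            term /= len(values)
            if ident == 1:
                num += term
            den += term
    return num / den
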