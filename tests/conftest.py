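import numpy as np
import pytest

from lichencoda import datasets, harmonize_units


@pytest.fixture(scope="session")
def survey():
    """Bundled 39-row lichen survey, units as printed (Fe in %w/w)."""
    return datasets.lichen_survey()


@pytest.fixture(scope="session")
def harmonized(survey):
    return harmonize_units(survey)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_compositions(rng, n, D):
    """Strictly positive random vectors spanning a few orders of magnitude."""
    return np.exp(rng.normal(0.0, 1.5, size=(n, D)))
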