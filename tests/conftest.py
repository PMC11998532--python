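import numpy as np
import pytest

from rnaplast.simulate import GeneratorSpec, generate_catalog
from rnaplast.stats import RegressionFit

#: Published summary of the natural-hairpin free-energy-vs-length regression
#: (slope kcal/mol/nt, intercept kcal/mol, the four natural hairpin lengths,
#: and the F statistic on (1, 2) df) used as the reference retention band.
REFERENCE_SLOPE = -0.42
REFERENCE_INTERCEPT = -2.84
REFERENCE_LENGTHS = (197, 32, 83, 61)
REFERENCE_F = 237.7


@pytest.fixture(scope="session")
def reference_fit() -> RegressionFit:
    return RegressionFit.from_summary(
        REFERENCE_SLOPE, REFERENCE_INTERCEPT, REFERENCE_LENGTHS, REFERENCE_F
    )


@pytest.fixture(scope="session")
def catalog_r100():
    """The default random-hairpin population at 100 replicates per cell.

    7 stem lengths x 11 complementarity levels x 100 replicates = 7,700
    folded hairpins; generated once per session (a few minutes).
    """
    return generate_catalog(GeneratorSpec(replicates=100, seed=0))


@pytest.fixture(scope="session")
def catalog_small():
    """A small folded catalog (2 replicates per cell) for unit tests."""
    return generate_catalog(GeneratorSpec(replicates=2, seed=1))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
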