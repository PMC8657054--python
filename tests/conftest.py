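import numpy as np
import pytest

from polycompare import SynthConfig, build_catalog, build_design, generate
from polycompare.catalog import catalog_nesting


@pytest.fixture(scope="session")
def lme_prepared():
    """Prepared design from a cohort generated under linear main effects."""
    cohort = generate(SynthConfig(n=400, model="Linear Main Effects Model", seed=7))
    return build_design(cohort)


@pytest.fixture(scope="session")
def catalog_cs(lme_prepared):
    return build_catalog(lme_prepared.range_box)


@pytest.fixture(scope="session")
def nesting_cs():
    return catalog_nesting(longitudinal=False)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
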