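import warnings

import pytest

from cardiowell import modeling
from cardiowell.cleansing import cleanse
from cardiowell.synth import generate_cohort

warnings.filterwarnings("ignore", message=".*Stochastic Optimizer.*")


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(800, seed=11)


@pytest.fixture(scope="session")
def clean_cohort(small_cohort):
    kept, _ = cleanse(small_cohort)
    return kept


@pytest.fixture(scope="session")
def tiny_model(clean_cohort):
    """A cheap fitted classifier for warehouse/analytics plumbing tests."""
    return modeling.fit_classifier(clean_cohort, modeling.TechniqueSpec("NB", "I"),
                                   seed=0)
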