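"""Shared fixtures: one large calibrated cohort reused across the suite."""

import pytest

from cmets.criteria import MetSClassifier
from cmets.derived import add_derived_measures
from cmets.scoring import CMetSScorer
from cmets.synthetic import GeneratorConfig, generate_cohort

COHORT_N = 50_000
COHORT_SEED = 1


@pytest.fixture(scope="session")
def cohort50k():
    """Default-configuration cohort of 50 000 subjects, derived columns added."""
    return add_derived_measures(generate_cohort(GeneratorConfig(n=COHORT_N, seed=COHORT_SEED)))


@pytest.fixture(scope="session")
def footnote_classifier(cohort50k):
    return MetSClassifier(criteria="table_footnote").fit(cohort50k)


@pytest.fixture(scope="session")
def classified50k(cohort50k, footnote_classifier):
    """Cohort with component flags under the summary-table footnote preset."""
    return footnote_classifier.transform(cohort50k)


@pytest.fixture(scope="session")
def scored50k(classified50k):
    """Classified cohort with z-scores and the cMetS column."""
    return CMetSScorer().fit_transform(classified50k)
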