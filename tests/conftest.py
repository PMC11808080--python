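"""Shared fixtures: small generated cohorts and derived tables."""

import pytest

from somnolog.orchestration import prepare_cohort_tables
from somnolog.synthetic_data import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 12-participant cohort with default study conditions."""
    return generate_cohort(GeneratorConfig(n_participants=12, seed=101))


@pytest.fixture(scope="session")
def small_tables(small_cohort):
    return prepare_cohort_tables(small_cohort)


@pytest.fixture(scope="session")
def clean_cohort():
    """A cohort with full annotation availability and high watch wear."""
    return generate_cohort(
        GeneratorConfig(
            n_participants=15, seed=77, missing_annotation_frac=0.0, wear_prob=0.97
        )
    )


@pytest.fixture(scope="session")
def clean_tables(clean_cohort):
    return prepare_cohort_tables(clean_cohort)
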