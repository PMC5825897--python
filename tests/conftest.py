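import numpy as np
import pytest

from connclass import (
    ClassifierSpec,
    PlantedEffect,
    SelectionConfig,
    SyntheticCohortConfig,
    generate_feature_dataset,
)


@pytest.fixture
def null_table():
    """24+24 subjects, 100 features, no planted group difference."""
    cohort = SyntheticCohortConfig(n_patients=24, n_controls=24, seed=11)
    table, _ = generate_feature_dataset(cohort, 100)
    return table


@pytest.fixture
def planted_table():
    """24+24 subjects, 5 strongly planted features (d=3) among 100."""
    cohort = SyntheticCohortConfig(n_patients=24, n_controls=24, seed=7)
    table, truth = generate_feature_dataset(
        cohort, 100, PlantedEffect(feature_ids=[0, 1, 2, 3, 4], effect_size=3.0)
    )
    return table, truth


@pytest.fixture
def linear_svm():
    return ClassifierSpec(family="linear_svm")


@pytest.fixture
def fs_config():
    return SelectionConfig(k=10)
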