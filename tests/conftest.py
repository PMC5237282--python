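import numpy as np
import pandas as pd
import pytest

from mirpan import ExpressionDataset, SimulationConfig, generate_cohort
from mirpan.datasets import OutcomeCoefficients


@pytest.fixture(scope="session")
def small_cohort():
    """A compact 4-class cohort exercised by several modules."""
    config = SimulationConfig(
        n_classes=4,
        samples_per_class=(40, 40, 40, 40),
        n_features=60,
        n_informative=12,
        class_effect_size=2.5,
        missing_feature_fraction=0.2,
        missing_rate_within_feature=0.1,
        n_treatments=5,
        seed=11,
    )
    return generate_cohort(config)


@pytest.fixture(scope="session")
def prognosis_cohort():
    """Cohort with a strong planted treatment structure for outcome tests."""
    config = SimulationConfig(
        n_classes=3,
        samples_per_class=(170, 170, 170),
        n_features=30,
        n_informative=10,
        class_effect_size=2.0,
        missing_feature_fraction=0.0,
        n_treatments=4,
        outcome_coefficients=OutcomeCoefficients(
            intercept=-2.2, age=-0.2, gender=0.1, ethnicity=0.1,
            treatment_scale=4.4, mirna_main=0.3, mirna_interaction=0.0,
        ),
        seed=5,
    )
    return generate_cohort(config)


@pytest.fixture
def toy_expression():
    values = pd.DataFrame(
        {
            "f1": [1.0, 2.0, 3.0, 4.0],
            "f2": [0.0, np.nan, 2.0, np.nan],
            "f3": [5.0, 5.0, 5.0, 5.0],
        },
        index=["s1", "s2", "s3", "s4"],
    )
    return ExpressionDataset(values=values)
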