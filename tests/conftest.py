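import datetime as dt

import numpy as np
import pytest

from dashcloud.intake import NutrientDensityProfile
from dashcloud.scoring import TargetSet


@pytest.fixture(scope="session")
def targets() -> TargetSet:
    return TargetSet.default()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20170712)


@pytest.fixture(scope="session")
def perfect_profile() -> NutrientDensityProfile:
    """Meets every default standard: full 9-point adherence."""
    return NutrientDensityProfile(
        total_fat=25.0,
        saturated_fat=5.0,
        protein=19.0,
        cholesterol=60.0,
        fiber=15.0,
        magnesium=250.0,
        calcium=600.0,
        potassium=2300.0,
        sodium=2000.0,
    )


@pytest.fixture(scope="session")
def failing_profile() -> NutrientDensityProfile:
    """Fails every component beyond its intermediate threshold: score 0."""
    return NutrientDensityProfile(
        total_fat=50.0,
        saturated_fat=20.0,
        protein=5.0,
        cholesterol=300.0,
        fiber=2.0,
        magnesium=50.0,
        calcium=100.0,
        potassium=400.0,
        sodium=5000.0,
    )


@pytest.fixture(scope="session")
def cohort_baseline_profile() -> NutrientDensityProfile:
    """Published cohort baseline means (intervention arm), already on the
    standardized bases; scores 2.0 under the default targets."""
    return NutrientDensityProfile(
        total_fat=37.9,
        saturated_fat=12.6,
        protein=16.0,
        cholesterol=172.2,
        fiber=9.1,
        magnesium=142.2,
        calcium=494.4,
        potassium=1318.0,
        sodium=3223.6,
    )


def make_profile(values: dict) -> NutrientDensityProfile:
    return NutrientDensityProfile(**values)
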