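import warnings

import numpy as np
import pytest

from prodrome.features import extract_hourly_features
from prodrome.impute import fill_type2
from prodrome.pipeline import day_label_frame
from prodrome.synthetic_cohort import CohortConfig, ShiftSpec, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Shared 4-participant cohort with a planted sleep shift and both
    missingness types."""
    cfg = CohortConfig(
        n_participants=4,
        relapse_fraction=0.5,
        days_per_participant=60,
        relapse_events_dist={1: 1.0},
        type2_missing_rate=0.25,
        type1_missing_rate=0.02,
        seed=7,
        signature={"sleep_duration": ShiftSpec("sd", 1.5, 0)},
    )
    events, calendars, gt = generate_cohort(cfg)
    return cfg, events, calendars, gt


@pytest.fixture(scope="session")
def small_features(small_cohort):
    _, events, calendars, _ = small_cohort
    return extract_hourly_features(events, calendars), calendars


@pytest.fixture(scope="session")
def small_imputed(small_features):
    fm, calendars = small_features
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fill_type2(fm, day_labels=day_label_frame(calendars)), calendars


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
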