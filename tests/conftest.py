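import dataclasses

import pandas as pd
import pytest

from nof1gest import CohortConfig, FeatureConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 12-participant default-condition cohort shared across tests."""
    cfg = dataclasses.replace(CohortConfig(), n_participants=12, seed=7)
    return cfg, generate_cohort(cfg)


@pytest.fixture(scope="session")
def noiseless_config():
    """Single-feature cohort with zero noise and a fixed vertex at week 33."""
    feat = FeatureConfig("hrv", baseline_mean=45.0, baseline_sd=0.0,
                         curvature_mean=0.03, curvature_sd=0.0,
                         noise_sd=0.0)
    return CohortConfig(n_participants=5, features=(feat,),
                        vertex_week_mean=33.0, vertex_week_sd=0.0,
                        missing_rate=0.0, event_rate=0.0,
                        subgroup_fractions={}, seed=11)


def make_participants(rows):
    """Participant table from (id, delivery, due, age, bmi, comps) tuples."""
    return pd.DataFrame(rows, columns=["participant_id", "delivery_date",
                                       "due_date", "age", "bmi",
                                       "complications"])


def make_observations(rows):
    """Observation table from (id, feature, day, value) tuples."""
    return pd.DataFrame(rows, columns=["participant_id", "feature",
                                       "day_rel_delivery", "value"])
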