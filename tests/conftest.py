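"""Shared fixtures: small synthetic cohorts and model-ready sample frames."""

import numpy as np
import pandas as pd
import pytest

from stresscast import features, synth


@pytest.fixture(scope="session")
def small_cohort():
    """A small but fully structured cohort for integration-style tests."""
    cfg = synth.CohortConfig(
        n_persons=6,
        n_days=160,
        min_participation_days=80,
        max_participation_days=160,
    )
    return synth.generate_cohort(cfg, seed=123)


@pytest.fixture(scope="session")
def small_samples(small_cohort):
    c = small_cohort
    return features.build_samples(
        c.stress, c.activity, c.weather, mode="nomothetic", persons=c.persons
    )


def make_regression_frame(X, y, person_id="p0", start="2014-01-01"):
    """Wrap a plain (X, y) regression problem in the sample-frame schema."""
    X = np.asarray(X, float)
    df = pd.DataFrame(X, columns=[f"f{i}" for i in range(X.shape[1])])
    df["y"] = np.asarray(y, float)
    df["person_id"] = person_id
    df["target_date"] = pd.date_range(start, periods=len(df)).date
    return df


@pytest.fixture
def regression_frame():
    return make_regression_frame
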