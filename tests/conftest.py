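import numpy as np
import pandas as pd
import pytest

import thermoflor as tf


@pytest.fixture(scope="session")
def small_cohort() -> pd.DataFrame:
    """Default small-flower cohort: 3 groups x 12 bees, seeded."""
    return tf.simulate_cohort(tf.CohortConfig(seed=11), tf.ArenaConfig.small())


@pytest.fixture(scope="session")
def series(small_cohort) -> pd.DataFrame:
    return tf.success_series(small_cohort)


@pytest.fixture(scope="session")
def testphase_tbl(small_cohort) -> pd.DataFrame:
    return tf.testphase_table(small_cohort)


@pytest.fixture(scope="session")
def full_fit(series):
    return tf.LearningCurveModel(series, tf.ModelSpec.full()).fit()


def make_series(rows) -> pd.DataFrame:
    """Helper: success series from (bee_id, group, x, theta) tuples."""
    df = pd.DataFrame(rows, columns=["bee_id", "group", "x", "theta"])
    df["success"] = np.sin(df["theta"]) ** 2
    return df[["bee_id", "group", "x", "success", "theta"]]
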