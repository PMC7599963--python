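import numpy as np
import pandas as pd
import pytest

from dwimicro import CohortTable, make_scheme


@pytest.fixture(scope="session")
def scheme61():
    """The study-like acquisition: 1 baseline + 61 directions at b=1000."""
    return make_scheme(n_dirs=61, bval=1000.0, n_b0=1)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def _patient_row(sid, group, **kw):
    row = dict(id=sid, group=group, sex="female", age=35.0,
               duration=10.0, cm_onset_months=np.nan,
               headache_freq=5.0, migraine_freq=3.0, aura=False, overuse=False)
    row.update(kw)
    return row


@pytest.fixture
def minimal_cohort_df():
    """One subject per group, with the group-specific field pattern."""
    return pd.DataFrame([
        dict(id="HC001", group="HC", sex="male", age=40.0,
             duration=np.nan, cm_onset_months=np.nan, headache_freq=np.nan,
             migraine_freq=np.nan, aura=np.nan, overuse=np.nan),
        _patient_row("EM001", "EM"),
        _patient_row("CM001", "CM", cm_onset_months=24.0,
                     headache_freq=20.0, migraine_freq=15.0),
    ])


@pytest.fixture
def minimal_cohort(minimal_cohort_df):
    return CohortTable(minimal_cohort_df)
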