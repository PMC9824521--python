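import numpy as np
import pandas as pd
import pytest

import adlstress as a

#: The worked schedule example from the study protocol, transcribed with its
#: printed labels (which include two activities outside the six-label set the
#: deployed system used, so the loader takes a custom activity set).
TABLE1_ROWS = [
    ("00:00", "07:00", "sleeping"),
    ("07:30", "08:00", "cooking"),
    ("08:00", "08:30", "eating_meals"),
    ("08:30", "09:00", "resting"),
    ("09:00", "18:00", "going_out"),
    ("18:00", "18:30", "cooking"),
    ("18:30", "19:30", "eating_meals"),
    ("19:30", "21:00", "resting"),
    ("21:00", "21:30", "bathing"),
    ("21:30", "23:00", "resting"),
    ("23:00", "24:00", "sleeping"),
]
TABLE1_ACTIVITY_SET = (
    "bathing", "cooking", "eating_meals", "going_out", "resting", "sleeping",
)
TABLE1_DATE = "2022-01-01"


def table1_frame() -> pd.DataFrame:
    day = pd.Timestamp(TABLE1_DATE)
    rows = []
    for start, end, label in TABLE1_ROWS:
        s = day + pd.Timedelta(hours=int(start[:2]), minutes=int(start[3:]))
        e = day + pd.Timedelta(hours=int(end[:2]), minutes=int(end[3:]))
        rows.append(("S01", s, e, label))
    return pd.DataFrame(rows, columns=["subject_id", "start", "end", "label"])


@pytest.fixture()
def table1_csv(tmp_path):
    path = tmp_path / "table1.csv"
    table1_frame().to_csv(path, index=False)
    return path


def small_config(**overrides):
    """A fast cohort: few subjects/days, coarse heart-rate cadence."""
    defaults = dict(n_households=2, n_days=4, hr_sample_period=60, seed=11)
    defaults.update(overrides)
    return a.CohortConfig(**defaults)


@pytest.fixture(scope="session")
def small_cohort():
    return a.simulate_cohort(small_config())


@pytest.fixture(scope="session")
def small_datasets(small_cohort):
    # The small cohort samples at 60 s, so widen the pair gap accordingly.
    return a.assemble(small_cohort, max_gap_s=120)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
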