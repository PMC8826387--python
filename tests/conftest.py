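import numpy as np
import pandas as pd
import pytest

from heterostat.covariates import ExamTable


def make_series_args(tsk, ta=None, included=None, start="2017-07-01T00:00"):
    """Timestamp grid + arrays for a TempSeries of len(tsk) readings."""
    tsk = np.asarray(tsk, float)
    n = len(tsk)
    t = np.datetime64(start, "ns") + np.arange(n) * np.timedelta64(10, "m")
    ta = np.full(n, 25.0) if ta is None else np.asarray(ta, float)
    included = np.ones(n, bool) if included is None else np.asarray(included, bool)
    return t, tsk, ta, included


@pytest.fixture
def toy_exam_table():
    """Two bats, complete covariates, classes 0–2 (for likelihood checks)."""
    df = pd.DataFrame(
        {
            "bat_id": ["a", "a", "b", "b"],
            "day": [20, 40, 20, 40],
            "cls": [1, 2, 0, 1],
            "treatment": ["T25", "T25", "T10", "T10"],
            "group_id": ["g1", "g1", "g2", "g2"],
            "mass_c": [0.5, -0.5, 1.0, -1.0],
            "delta_t_c": [0.2, -0.2, 0.6, -0.6],
            "mass_missing": [False] * 4,
            "delta_t_missing": [False] * 4,
        }
    )
    return ExamTable(df=df, mass_center=11.0, delta_t_center=4.0)
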