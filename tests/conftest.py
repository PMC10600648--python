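import numpy as np
import pandas as pd
import pytest

from lifespace import metrics_core, sensor_io
from lifespace.synthetic_data import ARMS, SimScenario, simulate_cohort

FIGURE_STREAM = """home_id,timestamp,sensor_id,sensor_kind,location,state
h1,2019-01-01T03:01:15,d1,door,frontdoor,1
h1,2019-01-01T03:01:20,d1,door,frontdoor,0
h1,2019-01-01T03:12:13,d1,door,frontdoor,1
h1,2019-01-01T03:13:01,m_bed,motion,bedroom1,1
h1,2019-01-01T03:20:32,m_liv,motion,livingroom,1
h1,2019-01-01T03:25:47,m_bed,motion,bedroom1,0
h1,2019-01-01T03:56:28,m_liv,motion,livingroom,0
"""


@pytest.fixture
def figure_events(tmp_path):
    """The worked single-morning example: one door cycle pair, one bedroom
    dwell and one overlapping living-room dwell."""
    path = tmp_path / "figure.csv"
    path.write_text(FIGURE_STREAM)
    return sensor_io.read_events(path)


@pytest.fixture(scope="session")
def small_cohort():
    """A small four-arm cohort shared by read-only tests."""
    scenario = SimScenario(n_homes={a: 3 for a in ARMS}, n_days=12, seed=11)
    return simulate_cohort(scenario)


@pytest.fixture(scope="session")
def small_cohort_daily(small_cohort):
    return metrics_core.daily_metrics_table(small_cohort.events, small_cohort.metadata)


def make_day_records(home_id, start, n_days, value=1.0, **extra):
    """Synthetic day-record rows with constant metrics, for cleaning tests."""
    dates = pd.date_range(start, periods=n_days, freq="D")
    df = pd.DataFrame(
        {
            "home_id": home_id,
            "date": dates,
            "tooh": value,
            "ilsa": value,
            "livingroom": value,
            "kitchen": value,
            "bathroom": value,
            "bedroom1": value,
            "pct_rooms_used": 50.0,
        }
    )
    for k, v in extra.items():
        df[k] = v
    return df


def basic_metadata(home_ids, site="OHSU", n_residents=1):
    rows = []
    for h in home_ids:
        rows.append(
            {
                "home_id": h,
                "n_residents": n_residents,
                "mci_home": False,
                "mean_age": 75.0,
                "n_female": 1 if n_residents == 1 else 1,
                "n_male": 0 if n_residents == 1 else 1,
                "n_white": n_residents,
                "n_other_ethnicity": 0,
                "mean_education": 15.0,
                "n_rooms": 6,
                "site": site,
                "move_dates": "",
            }
        )
    return pd.DataFrame(rows).set_index("home_id", drop=False)


@pytest.fixture
def no_reports():
    return pd.DataFrame(
        columns=["home_id", "week_start", "overnight_visitors", "away_overnight"]
    ).astype({"week_start": "datetime64[ns]"})
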