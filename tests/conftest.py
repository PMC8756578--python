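import datetime as dt

import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_frame(rows):
    """Build a canonical measurement frame from compact row tuples:
    (id, sex, birth, draw, creatinine[, kidney_dx])."""
    recs = []
    for row in rows:
        rid, sex, birth, draw, creat = row[:5]
        kidney = bool(row[5]) if len(row) > 5 else False
        recs.append(
            {
                "individual_id": rid,
                "sex": sex,
                "birth_date": pd.Timestamp(birth),
                "draw_date": pd.Timestamp(draw),
                "creatinine": float(creat),
                "kidney_dx": kidney,
            }
        )
    return pd.DataFrame(recs)


@pytest.fixture
def toy_frame():
    """Three healthy single-draw children, one per broad age band."""
    return make_frame(
        [
            ("a", "M", dt.date(2015, 1, 1), dt.date(2015, 7, 1), 0.26),
            ("b", "F", dt.date(2010, 1, 1), dt.date(2015, 7, 1), 0.38),
            ("c", "M", dt.date(2000, 1, 1), dt.date(2015, 7, 1), 0.80),
        ]
    )


@pytest.fixture(scope="session")
def default_cohort():
    """One default-scale synthetic cohort, shared across read-only tests."""
    from creatref.synthetic_cohort import SyntheticCohortConfig, generate_cohort

    config = SyntheticCohortConfig(seed=7)
    return config, generate_cohort(config)
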