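import numpy as np
import pandas as pd
import pytest

from drugprep.core import PLAUSIBILITY_COLUMNS, THERAPY_COLUMNS


def make_records(rows):
    """Build a therapy frame from partial dicts; absent fields are missing."""
    out = []
    for i, row in enumerate(rows):
        base = {
            "patient_id": 1,
            "product_code": "P1",
            "start": 0.0,
            "qty": np.nan,
            "ndd": np.nan,
            "numdays": np.nan,
            "dose_duration": np.nan,
        }
        base.update(row)
        out.append(base)
    return pd.DataFrame(out, columns=THERAPY_COLUMNS)


def make_plausibility(rows):
    out = []
    for row in rows:
        base = {
            "product_code": "P1",
            "drug_class": "drug",
            "qty_min": 1.0,
            "qty_max": 500.0,
            "ndd_min": 0.5,
            "ndd_max": 6.0,
            "dur_min": 1.0,
            "dur_max": 186.0,
            "default_qty": 56.0,
            "default_ndd": 2.0,
            "default_duration_days": 28.0,
        }
        base.update(row)
        out.append(base)
    return pd.DataFrame(out, columns=PLAUSIBILITY_COLUMNS)


def make_episodes(intervals, patient_id=1, drug_class="drug"):
    return pd.DataFrame(
        [
            {"patient_id": patient_id, "drug_class": drug_class, "start": float(s), "stop": float(e)}
            for s, e in intervals
        ],
        columns=["patient_id", "drug_class", "start", "stop"],
    )


def intervals_of(episodes):
    return [(float(s), float(e)) for s, e in zip(episodes["start"], episodes["stop"])]


@pytest.fixture
def plaus():
    return make_plausibility([{"product_code": "P1"}, {"product_code": "P2"}])
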