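"""Hand-built fixture matrices shared between unit and acceptance tests."""

from datetime import date, timedelta

import numpy as np
import pandas as pd

from prodrome.features import FeatureMatrix
from prodrome.schema import FEATURES, IMPUTABLE_FEATURES


def empty_grid(n_days=2, pid="P0", start=date(2023, 1, 2)):
    rows = []
    for d in range(n_days):
        for h in range(24):
            rows.append({"participant_id": pid, "date": start + timedelta(days=d), "hour": h})
    df = pd.DataFrame(rows)
    for f in FEATURES:
        df[f] = np.nan
    df["day_of_week"] = pd.to_datetime(df["date"]).dt.dayofweek.astype(float)
    df["hour_of_day"] = df["hour"].astype(float)
    df["fill_fraction"] = 0.0
    return df


def location_fixture():
    """A grid where hour 10 of day 1 is observed mostly in 'primary' and
    everything after it is fully missing; also a couple of observed text
    hours so hour-of-day means exist."""
    v = empty_grid()
    mask = pd.DataFrame(False, index=v.index, columns=list(IMPUTABLE_FEATURES))
    located_idx = v.index[(v["hour"] == 10) & (v["date"] == date(2023, 1, 2))][0]
    v.loc[located_idx, ["time_in_primary", "time_in_secondary", "time_in_other"]] = [
        3000.0, 600.0, 0.0,
    ]
    v.loc[located_idx, "distance_travelled"] = 0.2
    mask.loc[
        located_idx,
        ["time_in_primary", "time_in_secondary", "time_in_other", "distance_travelled"],
    ] = True
    for h in (3, 14):
        for d in range(2):
            i = v.index[(v["hour"] == h) & (v["date"] == date(2023, 1, 2) + timedelta(days=d))][0]
            v.loc[i, "n_sent_texts"] = float(d + 1)
            mask.loc[i, "n_sent_texts"] = True
    return FeatureMatrix(values=v, mask=mask), located_idx
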