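"""Two-type missing-data handling and the fill-fraction feature.

Type 1 (partially observed hour): unobserved features are set to 0 — the
device was alive, the behaviour simply did not occur.

Type 2 (fully missing hour): every feature filled with the participant's
hour-of-day mean computed from that participant's observed hours, except the
location dwell features, which put the full hour at the last recorded place
(carry-forward) with distance 0.

``fill_fraction`` = imputed / imputable features for the hour, so it is
exactly 1 on type-2 hours and < 1 everywhere else.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import FeatureMatrix
from .schema import IMPUTABLE_FEATURES, LABEL_DRH, LOCATION_FEATURES

logger = logging.getLogger(__name__)

_LOC = list(LOCATION_FEATURES)
_NONLOC = [f for f in IMPUTABLE_FEATURES if f not in _LOC and f != "distance_travelled"]


@dataclass
class ImputedFeatureMatrix:
    values: pd.DataFrame      # dense grid, fill_fraction finalized
    type2_flag: pd.Series     # per row
    report: dict              # per-participant imputation counts


def fill_type1(matrix: FeatureMatrix) -> FeatureMatrix:
    """Zero-fill unobserved features on partially observed hours.

    Fully missing (type-2 candidate) hours are left untouched for
    :func:`fill_type2`; ``fill_fraction`` is updated for the filled rows.
    """
    values = matrix.values.copy()
    mask = matrix.mask
    feats = list(IMPUTABLE_FEATURES)
    observed_any = mask.any(axis=1)
    n_imputed = (~mask[feats]).sum(axis=1)
    rows = observed_any.to_numpy()
    block = values.loc[rows, feats]
    values.loc[rows, feats] = block.where(mask.loc[rows, feats], 0.0)
    values.loc[rows, "fill_fraction"] = (n_imputed[rows] / len(feats)).to_numpy()
    values.loc[~rows, "fill_fraction"] = 1.0
    return FeatureMatrix(values=values, mask=mask)


def _hourly_means(values, mask, stat_rows):
    """Per (participant, hour-of-day, feature) means over observed hours."""
    obs = values.loc[stat_rows, ["participant_id", "hour"]].copy()
    data = values.loc[stat_rows, _NONLOC].where(mask.loc[stat_rows, _NONLOC])
    obs = pd.concat([obs, data], axis=1)
    by_hour = obs.groupby(["participant_id", "hour"], sort=True)[_NONLOC].mean()
    overall = obs.groupby("participant_id", sort=True)[_NONLOC].mean()
    return by_hour, overall


def fill_type2(
    matrix: FeatureMatrix,
    day_labels: pd.Series | None = None,
) -> ImputedFeatureMatrix:
    """Fill fully-missing hours and finalize the dense matrix.

    ``day_labels``, if given (MultiIndex (participant_id, date) -> label),
    restricts the hour-of-day statistics to healthy-baseline (DRH) days so the
    imputed baseline cannot absorb near-relapse behaviour.
    """
    m = fill_type1(matrix)
    values, mask = m.values, m.mask
    type2 = ~mask.any(axis=1)
    feats = list(IMPUTABLE_FEATURES)

    stat_rows = mask.any(axis=1)
    if day_labels is not None:
        key = pd.MultiIndex.from_frame(values[["participant_id", "date"]])
        lab = pd.Series(day_labels.reindex(key).to_numpy(), index=values.index)
        drh = lab == LABEL_DRH
        if (stat_rows & drh).any():
            stat_rows = stat_rows & drh

    by_hour, overall = _hourly_means(values, mask, stat_rows)
    t2 = values.loc[type2]
    if len(t2):
        key = pd.MultiIndex.from_frame(t2[["participant_id", "hour"]])
        filled = by_hour.reindex(key)
        missing_any = filled[_NONLOC].isna()
        if missing_any.to_numpy().any():
            fallback = overall.reindex(t2["participant_id"])
            n_fb = int(missing_any.to_numpy().sum())
            logger.info("fell back to all-hours means for %d cells", n_fb)
            filled = filled.where(~missing_any.to_numpy(), fallback.to_numpy())
        values.loc[type2, _NONLOC] = filled[_NONLOC].to_numpy()
        values.loc[type2, "distance_travelled"] = 0.0
        _carry_forward_location(values, mask, type2)
        values.loc[type2, "fill_fraction"] = 1.0

    remaining = values[feats].isna()
    if remaining.to_numpy().any():
        # participant observed nothing ever for a feature: zero as last resort
        logger.warning("zero-filled %d cells with no basis", int(remaining.to_numpy().sum()))
        values[feats] = values[feats].fillna(0.0)

    report = {}
    for pid, sub in values.groupby("participant_id", sort=True):
        rows = sub.index
        report[pid] = {
            "type2_hours": int(type2[rows].sum()),
            "type1_cells": int((~matrix.mask.loc[rows]).sum().sum() - type2[rows].sum() * len(feats)),
            "n_hours": int(len(rows)),
        }
    return ImputedFeatureMatrix(values=values, type2_flag=type2, report=report)


def _carry_forward_location(values, mask, type2):
    """Place each type-2 hour entirely at the last recorded location."""
    loc_obs = mask[_LOC].any(axis=1)
    for pid, sub in values.groupby("participant_id", sort=True):
        rows = sub.index
        obs_rows = rows[loc_obs[rows]]
        if len(obs_rows) == 0:
            # never saw a location: default to primary
            last_place = pd.Series("time_in_primary", index=rows)
        else:
            dominant = values.loc[obs_rows, _LOC].idxmax(axis=1)
            last_place = dominant.reindex(rows).ffill().bfill()
        t2_rows = rows[type2[rows]]
        for col in _LOC:
            values.loc[t2_rows, col] = np.where(last_place[t2_rows] == col, 3600.0, 0.0)


def write_report(imputed: ImputedFeatureMatrix, path) -> None:
    with open(path, "w") as fh:
        json.dump(imputed.report, fh, indent=2)
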