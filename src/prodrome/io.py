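"""Plain-text interchange formats: per-participant event CSVs (payload as
JSON), calendar CSV, feature matrices as CSV or Parquet, YAML configs."""

from __future__ import annotations

import json
from dataclasses import asdict
from datetime import date
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .features import FeatureMatrix
from .schema import FEATURES, IMPUTABLE_FEATURES
from .synthetic_cohort import EVENT_COLUMNS, CohortConfig, RelapseCalendar, ShiftSpec

_PAYLOAD_COLS = [c for c in EVENT_COLUMNS if c not in ("participant_id", "channel", "timestamp")]


def write_events_csv(events: pd.DataFrame, out_dir: str | Path) -> list[Path]:
    """One CSV per participant: participant_id, channel, timestamp, payload."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for pid, sub in events.groupby("participant_id", sort=True):
        payloads = []
        for rec in sub[_PAYLOAD_COLS].to_dict("records"):
            payloads.append(
                json.dumps(
                    {k: (v.isoformat() if isinstance(v, date) else v)
                     for k, v in rec.items()
                     if v is not None and not (isinstance(v, float) and np.isnan(v))},
                    sort_keys=True,
                )
            )
        frame = pd.DataFrame(
            {
                "participant_id": sub["participant_id"].to_numpy(),
                "channel": sub["channel"].to_numpy(),
                "timestamp": sub["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S.%f"),
                "payload": payloads,
            }
        )
        path = out_dir / f"events_{pid}.csv"
        frame.to_csv(path, index=False)
        paths.append(path)
    return paths


def read_events_csv(path_or_dir: str | Path) -> pd.DataFrame:
    p = Path(path_or_dir)
    files = sorted(p.glob("events_*.csv")) if p.is_dir() else [p]
    frames = []
    for f in files:
        raw = pd.read_csv(f)
        payload = raw["payload"].map(json.loads)
        ext = pd.DataFrame(list(payload))
        ext = ext.reindex(columns=_PAYLOAD_COLS)
        if "sleep_date" in ext.columns:
            ext["sleep_date"] = pd.to_datetime(ext["sleep_date"]).dt.date
        frames.append(
            pd.concat(
                [
                    raw[["participant_id", "channel"]].reset_index(drop=True),
                    pd.to_datetime(raw["timestamp"]).rename("timestamp").reset_index(drop=True),
                    ext.reset_index(drop=True),
                ],
                axis=1,
            )
        )
    return pd.concat(frames, ignore_index=True).reindex(columns=EVENT_COLUMNS)


def write_calendars_csv(calendars: dict, path: str | Path) -> None:
    rows = [
        {
            "participant_id": pid,
            "start_date": cal.start_date.isoformat(),
            "n_days": cal.n_days,
            "nr30_len": cal.nr30_len,
            "relapse_dates": ";".join(d.isoformat() for d in cal.relapse_dates),
        }
        for pid, cal in sorted(calendars.items())
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_calendars_csv(path: str | Path) -> dict:
    df = pd.read_csv(path, dtype={"relapse_dates": str}, keep_default_na=False)
    out = {}
    for rec in df.to_dict("records"):
        rdates = [
            date.fromisoformat(s) for s in str(rec["relapse_dates"]).split(";") if s
        ]
        out[rec["participant_id"]] = RelapseCalendar(
            rec["participant_id"],
            date.fromisoformat(rec["start_date"]),
            int(rec["n_days"]),
            rdates,
            int(rec["nr30_len"]),
        )
    return out


def write_feature_matrix(fm: FeatureMatrix, path: str | Path) -> None:
    """CSV or Parquet (by extension) plus a parallel ``.mask`` file."""
    path = Path(path)
    values = fm.values.copy()
    values["date"] = pd.to_datetime(values["date"]).dt.strftime("%Y-%m-%d")
    if path.suffix == ".parquet":
        values.to_parquet(path, index=False)
        fm.mask.to_parquet(path.with_suffix(".mask.parquet"), index=False)
    else:
        values.to_csv(path, index=False)
        fm.mask.to_csv(path.with_suffix(".mask.csv"), index=False)


def read_feature_matrix(path: str | Path) -> FeatureMatrix:
    path = Path(path)
    if path.suffix == ".parquet":
        values = pd.read_parquet(path)
        mask = pd.read_parquet(path.with_suffix(".mask.parquet"))
    else:
        values = pd.read_csv(path)
        mask = pd.read_csv(path.with_suffix(".mask.csv"))
    values["date"] = pd.to_datetime(values["date"]).dt.date
    return FeatureMatrix(values=values, mask=mask.astype(bool))


def config_to_yaml(config: CohortConfig, path: str | Path) -> None:
    d = asdict(config)
    d["start_date"] = config.start_date.isoformat()
    d["signature"] = {k: asdict(v) for k, v in config.signature.items()}
    d["relapse_events_dist"] = {int(k): float(v) for k, v in config.relapse_events_dist.items()}
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)


def config_from_yaml(path: str | Path) -> CohortConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    if "start_date" in d:
        d["start_date"] = date.fromisoformat(d["start_date"])
    if "signature" in d:
        d["signature"] = {k: ShiftSpec(**v) for k, v in (d["signature"] or {}).items()}
    if "relapse_events_dist" in d:
        d["relapse_events_dist"] = {int(k): float(v) for k, v in d["relapse_events_dist"].items()}
    return CohortConfig(**d)
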