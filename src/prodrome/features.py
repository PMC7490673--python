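"""Hourly feature extraction from raw sensing event streams.

Turns per-participant event logs into a participant x hour feature grid with
an observed/unobserved mask per imputable feature.  Location features come
from density-based place clustering (haversine metric) with the two largest
clusters tagged primary/secondary.

Conventions (documented, not dictated by the source data):

* Earth radius 6371.0088 km (IUGG mean).
* The interval between consecutive GPS fixes is attributed to the earlier
  fix's place; leading/trailing partial intervals extend to hour boundaries,
  so any hour with at least one fix has dwell summing to exactly 3600 s.
* Daily sleep estimates are replicated onto every hour of the day in which
  the device produced at least one non-sleep reading; an hour with no sensor
  readings at all therefore stays fully missing.
* Sleep onset is encoded on a continuous axis centred on midnight
  ((-12, 12], so 23:00 -> -1); wake stays in [0, 24).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import DBSCAN

from .schema import (
    CALL_SUBTYPES,
    FEATURES,
    FEATURE_CHANNEL,
    IMPUTABLE_FEATURES,
    TEXT_SUBTYPES,
    ZERO_DURATION_CALLS,
    encode_onset,
)

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0088

PRIMARY, SECONDARY, OTHER = "primary", "secondary", "other"


def mean_hourly_acceleration(samples) -> float:
    """Mean of per-sample vector norms over one hour of (ax, ay, az) triples.

    Raises on an empty hour: absence of readings is a missing value, never 0.
    """
    arr = np.asarray(samples, dtype=float)
    if arr.size == 0:
        raise ValueError("no acceleration samples in hour; feature is missing")
    return float(np.linalg.norm(arr.reshape(-1, 3), axis=1).mean())


def haversine_distance(p1, p2, radius_km: float = EARTH_RADIUS_KM):
    """Great-circle distance in km between (lat, lon) points in degrees.

    Accepts scalars or broadcastable arrays.
    """
    lat1, lon1 = np.asarray(p1[0], float), np.asarray(p1[1], float)
    lat2, lon2 = np.asarray(p2[0], float), np.asarray(p2[1], float)
    for lat in (lat1, lat2):
        if np.any(np.abs(lat) > 90.0):
            raise ValueError("latitude out of range [-90, 90]")
    for lon in (lon1, lon2):
        if np.any(np.abs(lon) > 180.0):
            raise ValueError("longitude out of range [-180, 180]")
    phi1, phi2 = np.radians(lat1), np.radians(lat2)
    dphi = phi2 - phi1
    dlmb = np.radians(lon2 - lon1)
    a = np.sin(dphi / 2.0) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlmb / 2.0) ** 2
    return radius_km * 2.0 * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


@dataclass
class PlaceClustering:
    labels: np.ndarray        # per fix: "primary" / "secondary" / "other"
    centroids: dict           # place -> (lat, lon) for primary/secondary
    member_counts: dict       # place -> number of member fixes


def cluster_locations(lat, lon, eps_km: float = 1.0, min_samples: int = 10) -> PlaceClustering:
    """DBSCAN over GPS fixes with the haversine metric; the two largest
    clusters become primary and secondary, everything else (smaller clusters
    and noise) is 'other'."""
    lat = np.asarray(lat, float)
    lon = np.asarray(lon, float)
    if lat.size == 0:
        raise ValueError("need at least one GPS fix")
    X = np.radians(np.column_stack([lat, lon]))
    db = DBSCAN(eps=eps_km / EARTH_RADIUS_KM, min_samples=min_samples, metric="haversine")
    raw = db.fit_predict(X)
    labels = np.full(lat.shape, OTHER, dtype=object)
    centroids, counts = {}, {}
    clusters = [c for c in np.unique(raw) if c >= 0]
    clusters.sort(key=lambda c: -(raw == c).sum())
    for place, c in zip((PRIMARY, SECONDARY), clusters):
        member = raw == c
        labels[member] = place
        centroids[place] = (float(lat[member].mean()), float(lon[member].mean()))
        counts[place] = int(member.sum())
    counts[OTHER] = int((labels == OTHER).sum())
    return PlaceClustering(labels=labels, centroids=centroids, member_counts=counts)


def hourly_location_features(times, labels, lat, lon, hour_start) -> tuple[dict, float]:
    """Dwell seconds per place plus distance travelled for one hour of
    time-ordered labeled fixes.

    The interval to the next fix belongs to the earlier fix's place; the
    leading partial interval belongs to the first fix, the trailing one to the
    last, so the dwell always sums to 3600 s when the hour has any fix.
    """
    times = pd.to_datetime(pd.Index(times))
    if len(times) == 0:
        raise ValueError("no fixes in hour")
    if not times.is_monotonic_increasing:
        raise ValueError("fixes must be time-ordered")
    hour_start = pd.Timestamp(hour_start)
    hour_end = hour_start + pd.Timedelta(hours=1)
    bounds = [hour_start] + list(times[1:]) + [hour_end]
    dwell = {PRIMARY: 0.0, SECONDARY: 0.0, OTHER: 0.0}
    for i, lab in enumerate(labels):
        dwell[lab] += (bounds[i + 1] - bounds[i]).total_seconds()
    lat = np.asarray(lat, float)
    lon = np.asarray(lon, float)
    dist = float(np.sum(haversine_distance((lat[:-1], lon[:-1]), (lat[1:], lon[1:])))) if len(times) > 1 else 0.0
    return dwell, dist


def _hour_grid(calendar) -> pd.DataFrame:
    hours = pd.date_range(calendar.start_date, periods=calendar.n_days * 24, freq="h")
    return pd.DataFrame(
        {
            "participant_id": calendar.participant_id,
            "date": hours.date,
            "hour": hours.hour,
            "_hour_ts": hours,
        }
    )


def _location_block(fixes: pd.DataFrame, eps_km, min_samples) -> pd.DataFrame:
    """Vectorised per-hour dwell + distance for one participant's fixes."""
    fixes = fixes.sort_values("timestamp", kind="mergesort")
    clustering = cluster_locations(
        fixes["lat"].to_numpy(), fixes["lon"].to_numpy(), eps_km, min_samples
    )
    t = fixes["timestamp"].reset_index(drop=True)
    lab = pd.Series(clustering.labels)
    hour_ts = t.dt.floor("h")
    hour_end = hour_ts + pd.Timedelta(hours=1)
    nxt = t.shift(-1)
    same_hour = hour_ts.shift(-1) == hour_ts
    seg_end = nxt.where(same_hour, hour_end)
    first_in_hour = hour_ts != hour_ts.shift(1)
    dwell = (seg_end - t).dt.total_seconds() + first_in_hour * (t - hour_ts).dt.total_seconds()

    ddf = pd.DataFrame({"_hour_ts": hour_ts, "place": lab.to_numpy(), "dwell": dwell})
    dw = ddf.pivot_table(index="_hour_ts", columns="place", values="dwell", aggfunc="sum").fillna(0.0)
    for place, col in ((PRIMARY, "time_in_primary"), (SECONDARY, "time_in_secondary"), (OTHER, "time_in_other")):
        dw[col] = dw.pop(place) if place in dw.columns else 0.0

    lat = fixes["lat"].to_numpy()
    lon = fixes["lon"].to_numpy()
    step = haversine_distance((lat[:-1], lon[:-1]), (lat[1:], lon[1:]))
    step = np.where(same_hour.to_numpy()[:-1], step, 0.0)
    dist = pd.Series(step, index=hour_ts.iloc[:-1]).groupby(level=0).sum()
    dw["distance_travelled"] = dist.reindex(dw.index).fillna(0.0)
    return dw[["time_in_primary", "time_in_secondary", "time_in_other", "distance_travelled"]]


@dataclass
class FeatureMatrix:
    """Hourly feature grid plus observed mask over the imputable features."""

    values: pd.DataFrame  # participant_id, date, hour + all FEATURES
    mask: pd.DataFrame    # same rows; boolean columns = IMPUTABLE_FEATURES


def extract_hourly_features(
    events: pd.DataFrame,
    calendars: dict,
    eps_km: float = 1.0,
    min_samples: int = 10,
) -> FeatureMatrix:
    """Build the hourly feature matrix (pre-imputation) for all participants.

    One row per hour of each participant's study window; features with no
    supporting channel events in the hour are NaN and marked unobserved.
    Events outside a participant's study window are dropped (count logged).
    """
    frames = []
    for pid, cal in sorted(calendars.items()):
        ev = events[events["participant_id"] == pid]
        grid = _hour_grid(cal)
        lo, hi = grid["_hour_ts"].iloc[0], grid["_hour_ts"].iloc[-1] + pd.Timedelta(hours=1)
        in_win = (ev["timestamp"] >= lo) & (ev["timestamp"] < hi)
        n_out = int((~in_win).sum())
        if n_out:
            logger.info("dropped %d events outside study window for %s", n_out, pid)
        ev = ev[in_win]
        frames.append(_featurize_participant(ev, grid, eps_km, min_samples))
    values = pd.concat(frames, ignore_index=True)
    mask = values[list(IMPUTABLE_FEATURES)].notna()
    # sleep is only "present" on device-alive hours: enforced below in
    # _featurize_participant, so the mask is just non-NaN-ness.
    values = values.drop(columns=["_hour_ts"])
    return FeatureMatrix(values=values, mask=mask)


def _featurize_participant(ev, grid, eps_km, min_samples) -> pd.DataFrame:
    hour_ts = ev["timestamp"].dt.floor("h")
    out = grid.copy()
    idx = out.set_index("_hour_ts").index

    def assign(series, col):
        out[col] = series.reindex(idx).to_numpy()

    # acceleration
    acc = ev[ev["channel"] == "acceleration"]
    if len(acc):
        norm = np.sqrt(acc["ax"] ** 2 + acc["ay"] ** 2 + acc["az"] ** 2)
        assign(norm.groupby(hour_ts[acc.index]).mean(), "mean_acceleration")
    else:
        out["mean_acceleration"] = np.nan

    # apps
    app = ev[ev["channel"] == "app"]
    if len(app):
        assign(app.groupby(hour_ts[app.index])["app_id"].nunique().astype(float), "n_unique_apps")
    else:
        out["n_unique_apps"] = np.nan

    # calls
    call = ev[ev["channel"] == "call"]
    call_hours = None
    if len(call):
        call_hours = pd.Index(hour_ts[call.index].unique())
        g = call.groupby([hour_ts[call.index], call["subtype"]])
        cnt = g.size().unstack(fill_value=0)
        dur = g["duration"].sum().unstack(fill_value=0.0).clip(upper=3600.0)
    for s in CALL_SUBTYPES:
        if call_hours is None:
            out[f"n_{s}_calls"] = np.nan
            out[f"{s}_call_duration"] = np.nan
            continue
        c = cnt[s] if s in cnt.columns else pd.Series(0.0, index=call_hours)
        assign(c.reindex(call_hours).fillna(0.0).astype(float), f"n_{s}_calls")
        if s in ZERO_DURATION_CALLS:
            d = pd.Series(0.0, index=call_hours)
        else:
            d = (dur[s] if s in dur.columns else pd.Series(0.0, index=call_hours)).reindex(call_hours).fillna(0.0)
        assign(d.astype(float), f"{s}_call_duration")

    # texts
    txt = ev[ev["channel"] == "text"]
    txt_hours = pd.Index(hour_ts[txt.index].unique()) if len(txt) else None
    cnt_t = (
        txt.groupby([hour_ts[txt.index], txt["subtype"]]).size().unstack(fill_value=0)
        if len(txt)
        else None
    )
    for s in TEXT_SUBTYPES:
        if txt_hours is None:
            out[f"n_{s}_texts"] = np.nan
        else:
            c = cnt_t[s] if s in cnt_t.columns else pd.Series(0.0, index=txt_hours)
            assign(c.reindex(txt_hours).fillna(0.0).astype(float), f"n_{s}_texts")

    # conversations, screen
    for ch, ncol, dcol in (
        ("conversation", "n_conversations", "conversation_duration"),
        ("screen", "n_screen_unlocks", "screen_duration"),
    ):
        sub = ev[ev["channel"] == ch]
        if len(sub):
            g = sub.groupby(hour_ts[sub.index])
            assign(g.size().astype(float), ncol)
            assign(g["duration"].sum().clip(upper=3600.0), dcol)
        else:
            out[ncol] = np.nan
            out[dcol] = np.nan

    # location
    gps = ev[ev["channel"] == "gps"]
    if len(gps):
        loc = _location_block(gps, eps_km, min_samples)
        for col in loc.columns:
            assign(loc[col], col)
    else:
        for col in ("time_in_primary", "time_in_secondary", "time_in_other", "distance_travelled"):
            out[col] = np.nan

    # sleep: replicate daily record onto device-alive hours only
    non_sleep_cols = [
        c
        for c in out.columns
        if c in FEATURE_CHANNEL and FEATURE_CHANNEL[c] != "sleep"
    ]
    alive = out[non_sleep_cols].notna().any(axis=1).to_numpy()
    slp = ev[ev["channel"] == "sleep"]
    if len(slp):
        by_day = slp.drop_duplicates(subset="sleep_date", keep="last").set_index("sleep_date")
        dur = out["date"].map(by_day["sleep_duration"]).to_numpy(dtype=float)
        onset = out["date"].map(by_day["sleep_onset"]).to_numpy(dtype=float)
        wake = out["date"].map(by_day["sleep_wake"]).to_numpy(dtype=float)
    else:
        dur = onset = wake = np.full(len(out), np.nan)
    out["sleep_duration"] = np.where(alive, dur, np.nan)
    out["sleep_onset"] = np.where(alive, encode_onset(onset), np.nan)
    out["sleep_wake"] = np.where(alive, wake % 24.0, np.nan)

    out["day_of_week"] = pd.to_datetime(out["date"]).dt.dayofweek.astype(float)
    out["hour_of_day"] = out["hour"].astype(float)
    out["fill_fraction"] = 0.0  # finalized during imputation
    return out[["participant_id", "date", "hour", "_hour_ts"] + list(FEATURES)]
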