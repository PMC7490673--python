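"""Seeded synthetic sensing-cohort generator.

Produces raw per-participant smartphone event streams (acceleration samples,
app polls, call/text logs, conversation episodes, GPS fixes, screen sessions,
daily sleep estimates) together with a relapse calendar, so that the whole
downstream pipeline is testable without any real study data.

Behaviour is driven by per-participant circadian rate curves with log-normal
participant-level random effects; near-relapse behaviour change is created by
:func:`inject_relapse_signature`, and the two missing-data mechanisms by
:func:`apply_missingness`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Mapping

import numpy as np
import pandas as pd

from .schema import (
    CALL_SUBTYPES,
    LABEL_DRH,
    LABEL_NR30,
    LABEL_RELAPSE,
    TEXT_SUBTYPES,
)

EVENT_COLUMNS = [
    "participant_id",
    "channel",
    "timestamp",
    "ax",
    "ay",
    "az",
    "app_id",
    "subtype",
    "duration",
    "lat",
    "lon",
    "sleep_date",
    "sleep_onset",
    "sleep_wake",
    "sleep_duration",
]

#: relative activity level by hour of day (drives every event-rate curve)
CIRCADIAN = np.array(
    [0.10, 0.05, 0.05, 0.05, 0.08, 0.15, 0.40, 0.70, 0.90, 1.00, 1.00, 1.00,
     1.00, 1.00, 1.00, 1.00, 1.00, 1.00, 0.95, 0.90, 0.80, 0.60, 0.35, 0.20]
)

#: base hourly rates at peak activity, before participant random effects
BASE_RATES = {
    "n_incoming_calls": 0.20,
    "n_outgoing_calls": 0.25,
    "n_missed_calls": 0.06,
    "n_rejected_calls": 0.03,
    "n_blocked_calls": 0.01,
    "n_received_texts": 0.60,
    "n_sent_texts": 0.50,
    "n_draft_texts": 0.06,
    "n_outbox_texts": 0.04,
    "n_failed_texts": 0.03,
    "n_queued_texts": 0.03,
    "n_conversations": 0.45,
    "n_screen_unlocks": 1.80,
}

#: log-normal duration scales (seconds) for duration-bearing events
DURATION_SCALE = {
    "call": 150.0,
    "conversation": 300.0,
    "screen": 180.0,
}

SLEEP_ONSET_MEAN = 23.5   # clock hours
SLEEP_ONSET_SD = 0.7
SLEEP_DURATION_MEAN = 7.5  # hours
SLEEP_DURATION_SD = 0.8

RANDOM_EFFECT_SIGMA = 0.35

COUNT_FEATURES = tuple(BASE_RATES)

#: features a signature shift may target, by mechanism
_MULTIPLICATIVE_OK = COUNT_FEATURES + (
    "conversation_duration",
    "screen_duration",
    "incoming_call_duration",
    "outgoing_call_duration",
    "mean_acceleration",
    "n_unique_apps",
)
_ADDITIVE_OK = ("sleep_duration", "sleep_onset", "sleep_wake")
SIGNATURE_FEATURES = tuple(sorted(set(_MULTIPLICATIVE_OK) | set(_ADDITIVE_OK)))


@dataclass(frozen=True)
class ShiftSpec:
    """One behavioural shift applied inside near-relapse windows.

    mode:
      ``multiplicative`` — event rates / durations scaled by ``value``;
      ``additive``       — sleep clock features shifted by ``value`` hours;
      ``sd``             — shift expressed in pooled hourly SD units, resolved
                           against the generator's own ground truth.
    """

    mode: str
    value: float
    ramp_days: int = 7

    def __post_init__(self):
        if self.mode not in ("multiplicative", "additive", "sd"):
            raise ValueError(f"unknown shift mode {self.mode!r}")
        if self.ramp_days < 0:
            raise ValueError("ramp_days must be >= 0")


@dataclass(frozen=True)
class CohortConfig:
    n_participants: int = 12
    relapse_fraction: float = 0.3
    days_per_participant: int = 300
    relapse_events_dist: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.78, 2: 0.05, 3: 0.17}
    )
    nr30_len: int = 30
    signature: Mapping[str, ShiftSpec] = field(default_factory=dict)
    type2_missing_rate: float = 0.0
    type1_missing_rate: float = 0.0
    start_date: date = date(2023, 1, 2)
    seed: int = 0

    def __post_init__(self):
        if self.n_participants < 1:
            raise ValueError("need at least one participant")
        for name, p in (
            ("relapse_fraction", self.relapse_fraction),
            ("type2_missing_rate", self.type2_missing_rate),
            ("type1_missing_rate", self.type1_missing_rate),
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.days_per_participant < 1 or self.nr30_len < 1:
            raise ValueError("counts must be >= 1")


@dataclass
class RelapseCalendar:
    participant_id: str
    start_date: date
    n_days: int
    relapse_dates: list
    nr30_len: int = 30

    @property
    def dates(self) -> list:
        return [self.start_date + timedelta(days=i) for i in range(self.n_days)]

    @property
    def day_labels(self) -> pd.Series:
        """Per-day label: NR30 iff 1 <= (relapse_date - day) <= nr30_len;
        the relapse day itself is neither NR30 nor DRH.  Overlapping windows
        merge naturally."""
        days = self.dates
        labels = np.array([LABEL_DRH] * self.n_days, dtype=object)
        for r in self.relapse_dates:
            for i, d in enumerate(days):
                delta = (r - d).days
                if 1 <= delta <= self.nr30_len:
                    if labels[i] != LABEL_RELAPSE:
                        labels[i] = LABEL_NR30
                elif delta == 0:
                    labels[i] = LABEL_RELAPSE
        return pd.Series(labels, index=pd.Index(days, name="date"), name="label")


def _participant_profile(rng: np.random.Generator) -> dict:
    eff = {k: float(np.exp(rng.normal(0.0, RANDOM_EFFECT_SIGMA))) for k in BASE_RATES}
    rates = {k: BASE_RATES[k] * eff[k] for k in BASE_RATES}
    home = (40.70 + rng.uniform(-0.1, 0.1), -74.00 + rng.uniform(-0.1, 0.1))
    bearing = rng.uniform(0, 2 * math.pi)
    away_km = rng.uniform(2.0, 8.0)
    away = (
        home[0] + (away_km / 111.0) * math.cos(bearing),
        home[1] + (away_km / (111.0 * math.cos(math.radians(home[0])))) * math.sin(bearing),
    )
    return {
        "rates": rates,
        "duration_mult": float(np.exp(rng.normal(0.0, RANDOM_EFFECT_SIGMA))),
        "accel_level": float(rng.uniform(0.05, 0.20)),
        "home": home,
        "away": away,
        "p_away_peak": float(np.clip(rng.uniform(0.3, 0.7), 0.0, 0.9)),
        "sleep_onset_mean": SLEEP_ONSET_MEAN + float(rng.normal(0.0, 0.5)),
        "sleep_duration_mean": SLEEP_DURATION_MEAN + float(rng.normal(0.0, 0.5)),
        "n_apps": int(rng.integers(8, 25)),
    }


def hourly_sd(feature: str, profile: dict) -> float:
    """Pooled hourly SD of a feature under the baseline generator, from the
    ground-truth parameters (used to resolve 'sd'-mode signature shifts)."""
    if feature == "sleep_duration":
        return SLEEP_DURATION_SD
    if feature in ("sleep_onset", "sleep_wake"):
        return SLEEP_ONSET_SD
    if feature in COUNT_FEATURES:
        lam = profile["rates"][feature] * CIRCADIAN
        return float(np.sqrt(lam.mean() + lam.var()))
    raise ValueError(
        f"'sd'-mode shifts are supported for sleep and count features only, not {feature!r}"
    )


def resolve_signature(signature: Mapping[str, ShiftSpec], profile: dict) -> dict:
    """Translate a signature with possible 'sd' entries into absolute
    multiplicative/additive shifts for one participant."""
    resolved = {}
    for feat, spec in signature.items():
        if feat not in SIGNATURE_FEATURES:
            raise ValueError(
                f"cannot inject a shift on {feat!r}; supported features: "
                f"{', '.join(SIGNATURE_FEATURES)}"
            )
        if spec.mode == "sd":
            sd = hourly_sd(feat, profile)
            if feat in _ADDITIVE_OK:
                resolved[feat] = ShiftSpec("additive", spec.value * sd, spec.ramp_days)
            else:
                lam_bar = float((profile["rates"][feat] * CIRCADIAN).mean())
                resolved[feat] = ShiftSpec(
                    "multiplicative", 1.0 + spec.value * sd / lam_bar, spec.ramp_days
                )
        else:
            if spec.mode == "additive" and feat not in _ADDITIVE_OK:
                raise ValueError(f"additive shifts only apply to sleep features, not {feat!r}")
            if spec.mode == "multiplicative" and feat not in _MULTIPLICATIVE_OK:
                raise ValueError(f"multiplicative shifts do not apply to {feat!r}")
            resolved[feat] = spec
    return resolved


def _poisson_events(rng, lam_per_hour, hour_starts, channel, pid, **payload_fns):
    """Draw Poisson event counts per hour and scatter timestamps uniformly."""
    counts = rng.poisson(lam_per_hour)
    total = int(counts.sum())
    if total == 0:
        return None
    starts = np.repeat(hour_starts, counts)
    ts = starts + pd.to_timedelta(rng.uniform(0, 3600, total), unit="s")
    rec = {"participant_id": pid, "channel": channel, "timestamp": ts}
    for col, fn in payload_fns.items():
        rec[col] = fn(total)
    return pd.DataFrame(rec)


def _generate_participant_events(
    pid: str, cal: RelapseCalendar, profile: dict, rng: np.random.Generator
) -> pd.DataFrame:
    n_hours = cal.n_days * 24
    hour_starts = pd.date_range(cal.start_date, periods=n_hours, freq="h")
    hod = hour_starts.hour.to_numpy()
    act = CIRCADIAN[hod]
    frames = []

    # acceleration: >=1 sample per hour so the device is "alive" every hour
    n_acc = 1 + rng.poisson(5, n_hours)
    tot = int(n_acc.sum())
    ts = np.repeat(hour_starts, n_acc) + pd.to_timedelta(rng.uniform(0, 3600, tot), unit="s")
    lvl = profile["accel_level"] * np.repeat(act, n_acc)
    frames.append(
        pd.DataFrame(
            {
                "participant_id": pid,
                "channel": "acceleration",
                "timestamp": ts,
                "ax": rng.normal(0.0, 1.0, tot) * lvl,
                "ay": rng.normal(0.0, 1.0, tot) * lvl,
                "az": 1.0 + rng.normal(0.0, 1.0, tot) * 0.3 * lvl,
            }
        )
    )

    # app polls every 15 minutes; breadth of app pool scales with activity
    poll_ts = np.repeat(hour_starts, 4) + np.tile(
        pd.to_timedelta([2, 17, 32, 47], unit="m"), n_hours
    )
    pool = np.maximum(1, np.ceil(profile["n_apps"] * np.repeat(act, 4)).astype(int))
    app_ids = rng.integers(0, pool)
    frames.append(
        pd.DataFrame(
            {
                "participant_id": pid,
                "channel": "app",
                "timestamp": poll_ts,
                "app_id": app_ids.astype(float),
            }
        )
    )

    # calls / texts / conversations / screen sessions
    dmult = profile["duration_mult"]
    for sub in CALL_SUBTYPES:
        lam = profile["rates"][f"n_{sub}_calls"] * act
        dur_fn = (
            (lambda n: rng.lognormal(math.log(DURATION_SCALE["call"] * dmult), 0.6, n))
            if sub in ("incoming", "outgoing")
            else (lambda n: np.zeros(n))
        )
        f = _poisson_events(
            rng, lam, hour_starts, "call", pid,
            subtype=lambda n, s=sub: np.full(n, s, dtype=object), duration=dur_fn,
        )
        if f is not None:
            frames.append(f)
    for sub in TEXT_SUBTYPES:
        lam = profile["rates"][f"n_{sub}_texts"] * act
        f = _poisson_events(
            rng, lam, hour_starts, "text", pid,
            subtype=lambda n, s=sub: np.full(n, s, dtype=object),
        )
        if f is not None:
            frames.append(f)
    f = _poisson_events(
        rng, profile["rates"]["n_conversations"] * act, hour_starts, "conversation", pid,
        duration=lambda n: np.minimum(
            rng.lognormal(math.log(DURATION_SCALE["conversation"] * dmult), 0.7, n), 3500.0
        ),
    )
    if f is not None:
        frames.append(f)
    f = _poisson_events(
        rng, profile["rates"]["n_screen_unlocks"] * act, hour_starts, "screen", pid,
        duration=lambda n: np.minimum(
            rng.lognormal(math.log(DURATION_SCALE["screen"] * dmult), 0.8, n), 3500.0
        ),
    )
    if f is not None:
        frames.append(f)

    # mobility: hourly home/away anchor, four fixes per hour with ~30 m jitter
    p_away = profile["p_away_peak"] * np.clip((act - 0.3) / 0.7, 0.0, 1.0)
    away = rng.random(n_hours) < p_away
    lat_anchor = np.where(away, profile["away"][0], profile["home"][0])
    lon_anchor = np.where(away, profile["away"][1], profile["home"][1])
    fix_ts = np.repeat(hour_starts, 4) + np.tile(
        pd.to_timedelta([5, 20, 35, 50], unit="m"), n_hours
    )
    nfix = 4 * n_hours
    frames.append(
        pd.DataFrame(
            {
                "participant_id": pid,
                "channel": "gps",
                "timestamp": fix_ts,
                "lat": np.repeat(lat_anchor, 4) + rng.normal(0, 3e-4, nfix),
                "lon": np.repeat(lon_anchor, 4) + rng.normal(0, 3e-4, nfix),
            }
        )
    )

    # one sleep estimate per day, stamped at noon
    onset = rng.normal(profile["sleep_onset_mean"], SLEEP_ONSET_SD, cal.n_days) % 24.0
    dur = np.maximum(rng.normal(profile["sleep_duration_mean"], SLEEP_DURATION_SD, cal.n_days), 0.5)
    wake = (onset + dur) % 24.0
    day_idx = pd.date_range(cal.start_date, periods=cal.n_days, freq="D")
    frames.append(
        pd.DataFrame(
            {
                "participant_id": pid,
                "channel": "sleep",
                "timestamp": day_idx + pd.Timedelta(hours=12),
                "sleep_date": day_idx.date,
                "sleep_onset": onset,
                "sleep_wake": wake,
                "sleep_duration": dur,
            }
        )
    )

    out = pd.concat(frames, ignore_index=True)
    return out.reindex(columns=EVENT_COLUMNS)


def _ramp_factors(cal: RelapseCalendar, ramp_days: int) -> pd.Series:
    """Per-NR30-day linear ramp factor in (0, 1]; 1 everywhere once ramped."""
    labels = cal.day_labels
    factors = pd.Series(0.0, index=labels.index)
    for r in cal.relapse_dates:
        start = r - timedelta(days=cal.nr30_len)
        for d in labels.index[labels == LABEL_NR30]:
            into = (d - start).days  # 0-based day index into this window
            if 0 <= into < cal.nr30_len:
                f = 1.0 if ramp_days <= 0 else min(1.0, (into + 1) / ramp_days)
                factors[d] = max(factors[d], f)
    return factors


_FEATURE_EVENT_SELECTOR = {
    **{f"n_{s}_calls": ("call", s) for s in CALL_SUBTYPES},
    **{f"n_{s}_texts": ("text", s) for s in TEXT_SUBTYPES},
    **{f"{s}_call_duration": ("call", s) for s in ("incoming", "outgoing")},
    "n_conversations": ("conversation", None),
    "conversation_duration": ("conversation", None),
    "n_screen_unlocks": ("screen", None),
    "screen_duration": ("screen", None),
    "mean_acceleration": ("acceleration", None),
    "n_unique_apps": ("app", None),
}


def inject_relapse_signature(
    events: pd.DataFrame,
    calendar: RelapseCalendar,
    signature: Mapping[str, ShiftSpec],
    seed: int = 0,
) -> pd.DataFrame:
    """Return a copy of ``events`` with the signature's behavioural shifts
    applied on NR30 days (with per-shift linear ramp-in); DRH days untouched.
    """
    if not signature:
        return events.copy()
    for feat in signature:
        if feat not in SIGNATURE_FEATURES:
            raise ValueError(
                f"cannot inject a shift on {feat!r}; supported features: "
                f"{', '.join(SIGNATURE_FEATURES)}"
            )
    rng = np.random.default_rng(seed)
    ev = events[events["participant_id"] == calendar.participant_id].copy()
    rest = events[events["participant_id"] != calendar.participant_id]
    day = pd.Series(ev["timestamp"].dt.date.to_numpy(), index=ev.index)

    drop = np.zeros(len(ev), dtype=bool)
    extra_frames = []
    for feat, spec in signature.items():
        ramp = _ramp_factors(calendar, spec.ramp_days)
        active = ramp[ramp > 0]
        if active.empty:
            continue
        day_factor = day.map(active).fillna(0.0).to_numpy()
        if spec.mode == "additive":
            sel = (ev["channel"] == "sleep").to_numpy() & (day_factor > 0)
            delta = spec.value * day_factor[sel]
            if feat == "sleep_duration":
                ev.loc[sel, "sleep_duration"] = np.maximum(
                    ev.loc[sel, "sleep_duration"] + delta, 0.0
                )
                ev.loc[sel, "sleep_wake"] = (ev.loc[sel, "sleep_wake"] + delta) % 24.0
            elif feat == "sleep_onset":
                ev.loc[sel, "sleep_onset"] = (ev.loc[sel, "sleep_onset"] + delta) % 24.0
                ev.loc[sel, "sleep_wake"] = (ev.loc[sel, "sleep_wake"] + delta) % 24.0
            else:  # sleep_wake
                ev.loc[sel, "sleep_wake"] = (ev.loc[sel, "sleep_wake"] + delta) % 24.0
                ev.loc[sel, "sleep_duration"] = np.maximum(
                    ev.loc[sel, "sleep_duration"] + delta, 0.0
                )
            continue

        channel, subtype = _FEATURE_EVENT_SELECTOR[feat]
        sel = (ev["channel"] == channel).to_numpy() & (day_factor > 0)
        if subtype is not None:
            sel &= (ev["subtype"] == subtype).to_numpy()
        if not sel.any():
            continue
        # effective multiplicative factor with ramp: 1 + (value-1)*ramp
        f_eff = 1.0 + (spec.value - 1.0) * day_factor[sel]
        if feat.endswith("_duration"):
            ev.loc[sel, "duration"] = ev.loc[sel, "duration"] * f_eff
        elif feat == "mean_acceleration":
            for c in ("ax", "ay", "az"):
                ev.loc[sel, c] = ev.loc[sel, c] * f_eff
        else:
            # count shift: thin below 1, superpose jittered copies above 1
            thin = np.minimum(f_eff, 1.0)
            keep = rng.random(thin.shape) < thin
            drop[np.flatnonzero(sel)[~keep]] = True
            over = np.maximum(f_eff - 1.0, 0.0)
            n_extra = rng.poisson(over)
            if n_extra.sum() > 0:
                src = ev.loc[sel].iloc[np.repeat(np.arange(sel.sum()), n_extra)].copy()
                jitter = pd.to_timedelta(rng.uniform(-900, 900, len(src)), unit="s")
                ts = src["timestamp"] + jitter
                # keep jittered copies inside their original day
                d0 = pd.to_datetime(src["timestamp"].dt.date)
                ts = ts.clip(lower=d0, upper=d0 + pd.Timedelta(hours=23, minutes=59))
                src["timestamp"] = ts
                if feat == "n_unique_apps":
                    src["app_id"] = src["app_id"] + 1000.0 + rng.integers(0, 50, len(src))
                extra_frames.append(src)

    ev = ev.loc[~drop]
    parts = [rest, ev] + extra_frames
    out = pd.concat(parts, ignore_index=True)
    return out.reindex(columns=EVENT_COLUMNS)


def apply_missingness(
    events: pd.DataFrame,
    type2_rate: float,
    type1_rate: float,
    seed: int = 0,
    windows: Mapping[str, tuple] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Remove whole participant-hours (type 2) and individual channel-hours
    (type 1) from the stream.

    Sleep records are exempt from type-2 removal: sleep is a *daily* derived
    quantity, and the featurizer only replicates it onto hours where some
    other channel was alive, so removed hours still end up fully missing.

    Returns the thinned events plus bookkeeping:
    ``{"type2": {pid: set of hour Timestamps}, "type1": {pid: set of (channel, hour)}}``.
    """
    if not 0.0 <= type2_rate <= 1.0 or not 0.0 <= type1_rate <= 1.0:
        raise ValueError("missingness rates must be in [0, 1]")
    rng = np.random.default_rng(seed)
    removed2: dict = {}
    removed1: dict = {}
    if type2_rate == 0.0 and type1_rate == 0.0:
        return events.copy(), {"type2": removed2, "type1": removed1}

    hour = events["timestamp"].dt.floor("h")
    keep = np.ones(len(events), dtype=bool)
    for pid, idx in events.groupby("participant_id", sort=True).groups.items():
        idx = np.asarray(idx)
        ph = hour.loc[idx]
        if windows is not None and pid in windows:
            start, n_days = windows[pid]
            grid = pd.date_range(start, periods=n_days * 24, freq="h")
        else:
            grid = pd.date_range(ph.min().floor("D"), ph.max().ceil("D"), freq="h")[:-1]
        if type2_rate > 0.0:
            dead = grid[rng.random(len(grid)) < type2_rate]
            removed2[pid] = set(dead)
            if len(dead):
                is_dead = ph.isin(set(dead)).to_numpy()
                not_sleep = (events["channel"].loc[idx] != "sleep").to_numpy()
                keep[idx[is_dead & not_sleep]] = False
        if type1_rate > 0.0:
            removed1[pid] = set()
            for ch in events["channel"].loc[idx].unique():
                dead = grid[rng.random(len(grid)) < type1_rate]
                removed1[pid].update((ch, h) for h in dead)
                if len(dead):
                    sel = (events["channel"].loc[idx] == ch).to_numpy() & ph.isin(
                        set(dead)
                    ).to_numpy()
                    keep[idx[sel]] = False
    return events.loc[keep].reset_index(drop=True), {"type2": removed2, "type1": removed1}


def generate_cohort(config: CohortConfig):
    """Generate event streams, relapse calendars and ground truth for a cohort.

    Returns ``(events, calendars, ground_truth)`` where ``events`` is one
    DataFrame over all participants, ``calendars`` maps participant id to
    :class:`RelapseCalendar`, and ``ground_truth`` records each participant's
    profile parameters, relapse status and resolved signature shifts.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_participants
    n_relapse = int(round(config.relapse_fraction * n))
    if config.signature and n_relapse < 1:
        warnings.warn("signature configured but no relapse participants", stacklevel=2)
    relapse_flags = np.zeros(n, dtype=bool)
    relapse_flags[rng.permutation(n)[:n_relapse]] = True

    counts = np.array(sorted(config.relapse_events_dist))
    probs = np.array([config.relapse_events_dist[c] for c in counts], dtype=float)
    probs = probs / probs.sum()

    events_frames, calendars, ground_truth = [], {}, {}
    for i in range(n):
        pid = f"P{i:03d}"
        prof = _participant_profile(rng)
        n_days = config.days_per_participant
        relapse_dates = []
        if relapse_flags[i]:
            k = int(rng.choice(counts, p=probs))
            lo = min(config.nr30_len + 10, max(n_days - 10, 2))
            hi = max(n_days - 2, lo + 1)
            for _ in range(200):
                cand = sorted(rng.integers(lo, hi, k).tolist())
                if all(b - a >= config.nr30_len + 15 for a, b in zip(cand, cand[1:])):
                    relapse_dates = [config.start_date + timedelta(days=int(c)) for c in cand]
                    break
            if not relapse_dates:  # crowded window: fall back to a single event
                relapse_dates = [
                    config.start_date + timedelta(days=int(rng.integers(lo, hi)))
                ]
        cal = RelapseCalendar(pid, config.start_date, n_days, relapse_dates, config.nr30_len)
        calendars[pid] = cal

        ev = _generate_participant_events(pid, cal, prof, rng)
        resolved = resolve_signature(config.signature, prof) if config.signature else {}
        if resolved and relapse_dates:
            ev = inject_relapse_signature(
                ev, cal, resolved, seed=int(rng.integers(0, 2**31))
            )
        events_frames.append(ev)
        ground_truth[pid] = {
            "relapse": bool(relapse_flags[i]),
            "profile": prof,
            "resolved_signature": resolved,
            "relapse_dates": relapse_dates,
        }

    events = pd.concat(events_frames, ignore_index=True)
    windows = {pid: (cal.start_date, cal.n_days) for pid, cal in calendars.items()}
    events, removed = apply_missingness(
        events,
        config.type2_missing_rate,
        config.type1_missing_rate,
        seed=int(rng.integers(0, 2**31)),
        windows=windows,
    )
    for pid in ground_truth:
        ground_truth[pid]["removed_type2_hours"] = removed["type2"].get(pid, set())
        ground_truth[pid]["removed_type1"] = removed["type1"].get(pid, set())
    events = events.sort_values(["participant_id", "timestamp"], kind="mergesort").reset_index(
        drop=True
    )
    return events, calendars, ground_truth
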