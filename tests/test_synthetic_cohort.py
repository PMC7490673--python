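"""Simulator contracts: determinism, calendar labelling, signature injection
and the two missingness mechanisms."""

import warnings
from datetime import date, timedelta

import numpy as np
import pandas as pd
import pytest

from prodrome.schema import LABEL_DRH, LABEL_NR30, LABEL_RELAPSE, encode_onset
from prodrome.synthetic_cohort import (
    CohortConfig,
    RelapseCalendar,
    ShiftSpec,
    apply_missingness,
    generate_cohort,
    inject_relapse_signature,
)


def _tiny_cfg(**kw):
    base = dict(
        n_participants=2,
        relapse_fraction=0.5,
        days_per_participant=50,
        relapse_events_dist={1: 1.0},
        seed=3,
    )
    base.update(kw)
    return CohortConfig(**base)


class TestCalendar:
    def test_nr30_boundary(self):
        r = date(2023, 3, 1)
        cal = RelapseCalendar("P", date(2023, 1, 1), 90, [r], nr30_len=30)
        lab = cal.day_labels
        assert lab[r] == LABEL_RELAPSE
        assert lab[r - timedelta(days=1)] == LABEL_NR30
        assert lab[r - timedelta(days=30)] == LABEL_NR30
        assert lab[r - timedelta(days=31)] == LABEL_DRH
        assert lab[r + timedelta(days=1)] == LABEL_DRH

    def test_overlapping_windows_merge(self):
        r1, r2 = date(2023, 2, 10), date(2023, 2, 25)
        cal = RelapseCalendar("P", date(2023, 1, 1), 90, [r1, r2], nr30_len=30)
        lab = cal.day_labels
        span = lab[(lab.index >= r1 - timedelta(days=30)) & (lab.index < r2)]
        # one contiguous labelled span, interrupted only by the first relapse day
        assert set(span.unique()) == {LABEL_NR30, LABEL_RELAPSE}
        assert (lab == LABEL_RELAPSE).sum() == 2

    def test_every_day_labelled_exactly_once(self, small_cohort):
        _, _, calendars, _ = small_cohort
        for cal in calendars.values():
            lab = cal.day_labels
            assert len(lab) == cal.n_days
            assert set(lab.unique()) <= {LABEL_DRH, LABEL_NR30, LABEL_RELAPSE}
            n_nr = (lab == LABEL_NR30).sum()
            # bounded by relapse count x window length
            assert n_nr <= len(cal.relapse_dates) * cal.nr30_len


class TestGenerate:
    def test_determinism(self):
        cfg = _tiny_cfg()
        e1, c1, _ = generate_cohort(cfg)
        e2, c2, _ = generate_cohort(cfg)
        pd.testing.assert_frame_equal(e1, e2)
        assert {p: c.relapse_dates for p, c in c1.items()} == {
            p: c.relapse_dates for p, c in c2.items()
        }

    def test_seed_changes_output(self):
        e1, _, _ = generate_cohort(_tiny_cfg(seed=3))
        e2, _, _ = generate_cohort(_tiny_cfg(seed=4))
        assert len(e1) != len(e2) or not e1["timestamp"].equals(e2["timestamp"])

    def test_timestamps_inside_window(self, small_cohort):
        _, events, calendars, _ = small_cohort
        for pid, cal in calendars.items():
            ev = events[events["participant_id"] == pid]
            lo = pd.Timestamp(cal.start_date)
            hi = lo + pd.Timedelta(days=cal.n_days)
            assert (ev["timestamp"] >= lo).all() and (ev["timestamp"] < hi).all()

    def test_one_sleep_record_per_day(self, small_cohort):
        _, events, _, _ = small_cohort
        slp = events[events["channel"] == "sleep"]
        assert not slp.duplicated(subset=["participant_id", "sleep_date"]).any()

    def test_durations_nonnegative(self, small_cohort):
        _, events, _, _ = small_cohort
        assert (events["duration"].dropna() >= 0).all()
        assert (events["sleep_duration"].dropna() >= 0).all()

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(n_participants=0)
        with pytest.raises(ValueError):
            CohortConfig(relapse_fraction=1.5)
        with pytest.raises(ValueError):
            CohortConfig(type2_missing_rate=-0.1)

    def test_signature_without_relapsers_warns(self):
        cfg = _tiny_cfg(
            relapse_fraction=0.0, signature={"n_conversations": ShiftSpec("multiplicative", 2.0)}
        )
        with pytest.warns(UserWarning, match="no relapse participants"):
            generate_cohort(cfg)


def _one_relapser():
    cfg = _tiny_cfg(n_participants=1, relapse_fraction=1.0, days_per_participant=70, seed=9)
    return generate_cohort(cfg)


class TestInjectSignature:
    def test_empty_signature_identity(self):
        events, calendars, _ = _one_relapser()
        cal = next(iter(calendars.values()))
        out = inject_relapse_signature(events, cal, {})
        pd.testing.assert_frame_equal(out, events)

    def test_multiplicative_zero_annihilates(self):
        events, calendars, _ = _one_relapser()
        cal = next(iter(calendars.values()))
        out = inject_relapse_signature(
            events, cal, {"n_conversations": ShiftSpec("multiplicative", 0.0, ramp_days=0)}
        )
        lab = cal.day_labels
        nr_days = set(lab.index[lab == LABEL_NR30])
        conv = out[out["channel"] == "conversation"]
        assert not conv["timestamp"].dt.date.isin(nr_days).any()
        # DRH conversations untouched
        before = events[events["channel"] == "conversation"]
        drh_days = set(lab.index[lab == LABEL_DRH])
        assert conv["timestamp"].dt.date.isin(drh_days).sum() == before[
            "timestamp"
        ].dt.date.isin(drh_days).sum()

    def test_additive_sleep_onset_shift(self):
        events, calendars, _ = _one_relapser()
        cal = next(iter(calendars.values()))
        out = inject_relapse_signature(
            events, cal, {"sleep_onset": ShiftSpec("additive", 2.0, ramp_days=0)}
        )
        lab = cal.day_labels
        slp = out[out["channel"] == "sleep"]
        sl_lab = slp["sleep_date"].map(lab)
        on = encode_onset(slp["sleep_onset"].to_numpy())
        nr = on[(sl_lab == LABEL_NR30).to_numpy()]
        drh = on[(sl_lab == LABEL_DRH).to_numpy()]
        assert abs(nr.mean() - drh.mean() - 2.0) < 0.5

    def test_unknown_feature_rejected(self):
        events, calendars, _ = _one_relapser()
        cal = next(iter(calendars.values()))
        with pytest.raises(ValueError, match="supported features"):
            inject_relapse_signature(events, cal, {"nonsense": ShiftSpec("multiplicative", 2.0)})

    def test_ramp_scales_in(self):
        events, calendars, _ = _one_relapser()
        cal = next(iter(calendars.values()))
        full = inject_relapse_signature(
            events, cal, {"n_sent_texts": ShiftSpec("multiplicative", 4.0, ramp_days=0)}, seed=5
        )
        ramped = inject_relapse_signature(
            events, cal, {"n_sent_texts": ShiftSpec("multiplicative", 4.0, ramp_days=30)}, seed=5
        )
        lab = cal.day_labels
        nr_days = set(lab.index[lab == LABEL_NR30])

        def n_sent(df):
            sub = df[(df["channel"] == "text") & (df["subtype"] == "sent")]
            return sub["timestamp"].dt.date.isin(nr_days).sum()

        assert n_sent(full) > n_sent(ramped) > n_sent(events)


def _daily_sleep_d(events, cal):
    slp = events[events["channel"] == "sleep"]
    lab = slp["sleep_date"].map(cal.day_labels)
    a = slp.loc[(lab == LABEL_NR30).to_numpy(), "sleep_duration"].to_numpy()
    b = slp.loc[(lab == LABEL_DRH).to_numpy(), "sleep_duration"].to_numpy()
    na, nb = len(a), len(b)
    pooled = np.sqrt(((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2))
    return (a.mean() - b.mean()) / pooled


class TestEffectRecovery:
    def test_sleep_shift_recovers_effect_size(self):
        cfg = CohortConfig(
            n_participants=20,
            relapse_fraction=1.0,
            days_per_participant=80,
            relapse_events_dist={1: 1.0},
            seed=21,
            signature={"sleep_duration": ShiftSpec("sd", 1.5, ramp_days=0)},
        )
        events, calendars, _ = generate_cohort(cfg)
        ds = [
            _daily_sleep_d(events[events["participant_id"] == pid], cal)
            for pid, cal in calendars.items()
        ]
        assert abs(np.mean(ds) - 1.5) < 0.3

    def test_effect_monotone_in_shift(self):
        means = []
        for shift in (0.5, 1.0, 2.0):
            cfg = CohortConfig(
                n_participants=8,
                relapse_fraction=1.0,
                days_per_participant=70,
                relapse_events_dist={1: 1.0},
                seed=31,
                signature={"sleep_duration": ShiftSpec("sd", shift, ramp_days=0)},
            )
            events, calendars, _ = generate_cohort(cfg)
            means.append(
                np.mean(
                    [
                        _daily_sleep_d(events[events["participant_id"] == pid], cal)
                        for pid, cal in calendars.items()
                    ]
                )
            )
        assert means[0] < means[1] < means[2]

    def test_no_signature_no_effect(self):
        cfg = CohortConfig(
            n_participants=8,
            relapse_fraction=1.0,
            days_per_participant=70,
            relapse_events_dist={1: 1.0},
            seed=41,
        )
        events, calendars, _ = generate_cohort(cfg)
        ds = [
            _daily_sleep_d(events[events["participant_id"] == pid], cal)
            for pid, cal in calendars.items()
        ]
        assert abs(np.mean(ds)) < 0.25


class TestMissingness:
    def test_zero_rates_identity(self, small_cohort):
        _, events, _, _ = small_cohort
        out, removed = apply_missingness(events, 0.0, 0.0, seed=1)
        pd.testing.assert_frame_equal(out, events)
        assert removed == {"type2": {}, "type1": {}}

    def test_type2_fraction_matches_rate(self):
        events, calendars, _ = _one_relapser()
        cal = next(iter(calendars.values()))
        windows = {cal.participant_id: (cal.start_date, cal.n_days)}
        _, removed = apply_missingness(events, 0.25, 0.0, seed=2, windows=windows)
        frac = len(removed["type2"][cal.participant_id]) / (cal.n_days * 24)
        # binomial tolerance: sd ~ sqrt(.25*.75/1680) ~ 0.011
        assert abs(frac - 0.25) < 0.04

    def test_type2_removes_all_nonsleep_events(self):
        events, calendars, _ = _one_relapser()
        cal = next(iter(calendars.values()))
        out, removed = apply_missingness(events, 0.3, 0.0, seed=3)
        dead = removed["type2"][cal.participant_id]
        hours = out["timestamp"].dt.floor("h")
        in_dead = hours.isin(dead)
        assert (out.loc[in_dead, "channel"] == "sleep").all()

    def test_rates_validated(self, small_cohort):
        _, events, _, _ = small_cohort
        with pytest.raises(ValueError):
            apply_missingness(events, 1.5, 0.0)
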