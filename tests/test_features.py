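"""Featurizer contracts: acceleration norms, haversine distances, place
clustering, dwell/distance accounting and the hourly matrix itself."""

import math
from datetime import date

import numpy as np
import pandas as pd
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st

from prodrome.features import (
    EARTH_RADIUS_KM,
    cluster_locations,
    extract_hourly_features,
    haversine_distance,
    hourly_location_features,
    mean_hourly_acceleration,
)
from prodrome.schema import IMPUTABLE_FEATURES
from prodrome.synthetic_cohort import EVENT_COLUMNS, RelapseCalendar


class TestAcceleration:
    def test_345_norm(self):
        assert mean_hourly_acceleration([(3, 4, 0)]) == pytest.approx(5.0)

    def test_mean_of_equal_norms(self):
        assert mean_hourly_acceleration([(3, 4, 0), (0, 0, 5)]) == pytest.approx(5.0)

    def test_brute_force_oracle(self, rng):
        samples = rng.normal(size=(100, 3))
        oracle = sum(math.sqrt(x * x + y * y + z * z) for x, y, z in samples) / 100
        assert mean_hourly_acceleration(samples) == pytest.approx(oracle, abs=1e-12)

    def test_empty_hour_is_missing_not_zero(self):
        with pytest.raises(ValueError, match="missing"):
            mean_hourly_acceleration([])


def _sloc_oracle(p1, p2):
    """Spherical law of cosines — independent great-circle formula."""
    la1, lo1, la2, lo2 = map(math.radians, (*p1, *p2))
    c = math.sin(la1) * math.sin(la2) + math.cos(la1) * math.cos(la2) * math.cos(lo2 - lo1)
    return EARTH_RADIUS_KM * math.acos(min(1.0, max(-1.0, c)))


class TestHaversine:
    def test_zero_distance(self):
        assert haversine_distance((12.3, 45.6), (12.3, 45.6)) == pytest.approx(0.0)

    def test_equatorial_antipodes(self):
        assert haversine_distance((0, 0), (0, 180)) == pytest.approx(
            math.pi * EARTH_RADIUS_KM, rel=1e-9
        )

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            haversine_distance((91, 0), (0, 0))
        with pytest.raises(ValueError):
            haversine_distance((0, 0), (0, 181))

    @settings(max_examples=100, deadline=None)
    @given(
        la1=st.floats(-85, 85), lo1=st.floats(-179, 179),
        la2=st.floats(-85, 85), lo2=st.floats(-179, 179),
    )
    def test_matches_law_of_cosines_oracle(self, la1, lo1, la2, lo2):
        d = float(haversine_distance((la1, lo1), (la2, lo2)))
        o = _sloc_oracle((la1, lo1), (la2, lo2))
        # the law-of-cosines oracle itself is ill-conditioned below ~10 m
        assume(o > 0.01)
        assert d == pytest.approx(o, rel=1e-6)


class TestClustering:
    def test_single_point_cluster(self, rng):
        lat = np.full(50, 40.0) + rng.normal(0, 1e-5, 50)
        lon = np.full(50, -74.0) + rng.normal(0, 1e-5, 50)
        pc = cluster_locations(lat, lon)
        assert (pc.labels == "primary").all()
        assert "secondary" not in pc.member_counts

    def test_two_blobs_and_noise(self, rng):
        lat = np.concatenate(
            [40.0 + rng.normal(0, 1e-4, 40), 40.09 + rng.normal(0, 1e-4, 20),
             41.0 + np.arange(5) * 0.5]
        )
        lon = np.concatenate(
            [-74.0 + rng.normal(0, 1e-4, 40), -74.0 + rng.normal(0, 1e-4, 20),
             -73.0 + np.arange(5) * 0.5]
        )
        pc = cluster_locations(lat, lon)
        assert (pc.labels[:40] == "primary").all()
        assert (pc.labels[40:60] == "secondary").all()
        assert (pc.labels[60:] == "other").all()
        assert pc.member_counts["primary"] >= pc.member_counts["secondary"] >= 10

    def test_below_min_samples_all_other(self):
        pc = cluster_locations(np.full(9, 40.0), np.full(9, -74.0))
        assert (pc.labels == "other").all()

    def test_duplication_stability(self, rng):
        lat = np.concatenate([40.0 + rng.normal(0, 1e-4, 30), 40.05 + rng.normal(0, 1e-4, 15)])
        lon = np.full(45, -74.0)
        a = cluster_locations(lat, lon)
        b = cluster_locations(np.tile(lat, 2), np.tile(lon, 2))
        assert (b.labels[:45] == a.labels).all() and (b.labels[45:] == a.labels).all()


class TestLocationHour:
    def test_stationary_full_hour(self):
        ts = pd.to_datetime(["2023-01-01 10:05", "2023-01-01 10:30", "2023-01-01 10:55"])
        dwell, dist = hourly_location_features(
            ts, ["primary"] * 3, [40.0] * 3, [-74.0] * 3, "2023-01-01 10:00"
        )
        assert dwell["primary"] == pytest.approx(3600.0)
        assert dwell["secondary"] == 0 and dwell["other"] == 0
        assert dist == pytest.approx(0.0)

    def test_two_fixes_one_km(self):
        ts = pd.to_datetime(["2023-01-01 10:10", "2023-01-01 10:40"])
        lat2 = 40.0 + 1.0 / 111.1949266  # ~1 km north
        _, dist = hourly_location_features(
            ts, ["primary", "other"], [40.0, lat2], [-74.0, -74.0], "2023-01-01 10:00"
        )
        assert dist == pytest.approx(1.0, rel=1e-3)

    def test_walk_distance_matches_pairwise_oracle(self, rng):
        ts = pd.date_range("2023-01-01 09:00", periods=10, freq="6min")
        lat = 40.0 + np.cumsum(rng.normal(0, 1e-3, 10))
        lon = -74.0 + np.cumsum(rng.normal(0, 1e-3, 10))
        _, dist = hourly_location_features(ts, ["other"] * 10, lat, lon, "2023-01-01 09:00")
        oracle = sum(
            _sloc_oracle((lat[i], lon[i]), (lat[i + 1], lon[i + 1])) for i in range(9)
        )
        assert dist == pytest.approx(oracle, rel=1e-5)

    def test_single_fix_whole_hour(self):
        dwell, dist = hourly_location_features(
            pd.to_datetime(["2023-01-01 10:42"]), ["secondary"], [40.0], [-74.0],
            "2023-01-01 10:00",
        )
        assert dwell["secondary"] == pytest.approx(3600.0)
        assert dist == 0.0


def _mini_events():
    """Two-day, one-participant stream built by hand."""
    rows = []

    def add(channel, ts, **payload):
        rows.append({"participant_id": "P0", "channel": channel,
                     "timestamp": pd.Timestamp(ts), **payload})

    # hour 10 on day 1: two outgoing calls, some accel, one gps fix
    add("call", "2023-01-02 10:05", subtype="outgoing", duration=60.0)
    add("call", "2023-01-02 10:25", subtype="outgoing", duration=30.0)
    add("acceleration", "2023-01-02 10:07", ax=3.0, ay=4.0, az=0.0)
    add("gps", "2023-01-02 10:15", lat=40.0, lon=-74.0)
    add("text", "2023-01-02 11:30", subtype="sent")
    add("text", "2023-01-02 11:31", subtype="sent")
    add("text", "2023-01-02 11:40", subtype="received")
    add("app", "2023-01-02 12:01", app_id=1.0)
    add("app", "2023-01-02 12:16", app_id=2.0)
    add("app", "2023-01-02 12:31", app_id=1.0)
    add("sleep", "2023-01-02 12:00", sleep_date=date(2023, 1, 2),
        sleep_onset=23.0, sleep_wake=7.0, sleep_duration=8.0)
    df = pd.DataFrame(rows)
    return df.reindex(columns=EVENT_COLUMNS)


class TestExtractHourly:
    @pytest.fixture()
    def fm(self):
        cal = RelapseCalendar("P0", date(2023, 1, 2), 2, [])
        return extract_hourly_features(_mini_events(), {"P0": cal})

    def test_call_counts_and_durations(self, fm):
        row = fm.values[(fm.values["date"] == date(2023, 1, 2)) & (fm.values["hour"] == 10)].iloc[0]
        assert row["n_outgoing_calls"] == 2
        assert row["outgoing_call_duration"] == pytest.approx(90.0)
        assert row["n_incoming_calls"] == 0  # observed zero: the channel was alive
        assert fm.mask.loc[row.name, "n_incoming_calls"]

    def test_text_counts(self, fm):
        row = fm.values[(fm.values["date"] == date(2023, 1, 2)) & (fm.values["hour"] == 11)].iloc[0]
        assert row["n_sent_texts"] == 2 and row["n_received_texts"] == 1

    def test_unique_apps(self, fm):
        row = fm.values[(fm.values["date"] == date(2023, 1, 2)) & (fm.values["hour"] == 12)].iloc[0]
        assert row["n_unique_apps"] == 2

    def test_empty_hour_fully_unobserved(self, fm):
        row = fm.values[(fm.values["date"] == date(2023, 1, 3)) & (fm.values["hour"] == 5)].iloc[0]
        assert not fm.mask.loc[row.name].any()

    def test_sleep_replicated_to_alive_hours_only(self, fm):
        d1 = fm.values[fm.values["date"] == date(2023, 1, 2)]
        alive = fm.mask.loc[d1.index].drop(
            columns=["sleep_duration", "sleep_onset", "sleep_wake"]
        ).any(axis=1)
        assert (d1.loc[alive.to_numpy(), "sleep_duration"] == 8.0).all()
        assert d1.loc[~alive.to_numpy(), "sleep_duration"].isna().all()
        # onset 23:00 encoded on the midnight-centred axis
        assert (d1.loc[alive.to_numpy(), "sleep_onset"] == -1.0).all()

    def test_context_features(self, fm):
        row = fm.values[(fm.values["date"] == date(2023, 1, 2)) & (fm.values["hour"] == 10)].iloc[0]
        assert row["day_of_week"] == 0  # a Monday
        assert row["hour_of_day"] == 10

    def test_permutation_invariance(self):
        cal = RelapseCalendar("P0", date(2023, 1, 2), 2, [])
        ev = _mini_events()
        shuffled = ev.sample(frac=1.0, random_state=5).reset_index(drop=True)
        a = extract_hourly_features(ev, {"P0": cal})
        b = extract_hourly_features(shuffled, {"P0": cal})
        pd.testing.assert_frame_equal(a.values, b.values)

    def test_out_of_window_events_dropped(self):
        cal = RelapseCalendar("P0", date(2023, 1, 2), 1, [])  # second day out of window
        fm = extract_hourly_features(_mini_events(), {"P0": cal})
        assert len(fm.values) == 24


class TestDwellConservation:
    def test_dwell_sums_bounded_on_simulated_data(self, small_features):
        fm, _ = small_features
        loc = fm.values[["time_in_primary", "time_in_secondary", "time_in_other"]].dropna()
        total = loc.sum(axis=1)
        assert (total <= 3600.0 + 1e-6).all()
        # simulator emits fixes every hour it emits anything: equality holds
        assert np.allclose(total, 3600.0)

    def test_mask_matches_nan_pattern(self, small_features):
        fm, _ = small_features
        assert (fm.mask == fm.values[list(IMPUTABLE_FEATURES)].notna()).all().all()
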