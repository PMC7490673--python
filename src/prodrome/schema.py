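"""Canonical feature schema shared by the simulator, featurizer and models.

The hourly feature vector has a fixed column order.  Three columns
(``day_of_week``, ``hour_of_day``, ``fill_fraction``) are *context* features:
they are always defined and are never imputed, so they are excluded from the
fill-fraction denominator.  Everything else is *imputable*.
"""

from __future__ import annotations

CHANNELS = (
    "acceleration",
    "app",
    "call",
    "text",
    "screen",
    "conversation",
    "gps",
    "sleep",
)

CALL_SUBTYPES = ("incoming", "outgoing", "missed", "rejected", "blocked")
TEXT_SUBTYPES = ("received", "sent", "draft", "outbox", "failed", "queued")

#: call subtypes whose duration is structurally zero (kept in the schema so the
#: models see explicit zeros)
ZERO_DURATION_CALLS = ("missed", "rejected", "blocked")

LOCATION_FEATURES = (
    "time_in_primary",
    "time_in_secondary",
    "time_in_other",
)

SLEEP_FEATURES = ("sleep_duration", "sleep_onset", "sleep_wake")

CONTEXT_FEATURES = ("day_of_week", "hour_of_day", "fill_fraction")

FEATURES = (
    ("mean_acceleration", "n_unique_apps")
    + tuple(f"n_{s}_calls" for s in CALL_SUBTYPES)
    + tuple(f"{s}_call_duration" for s in CALL_SUBTYPES)
    + ("n_conversations", "conversation_duration")
    + LOCATION_FEATURES
    + ("distance_travelled",)
    + ("n_screen_unlocks", "screen_duration")
    + SLEEP_FEATURES
    + tuple(f"n_{s}_texts" for s in TEXT_SUBTYPES)
    + CONTEXT_FEATURES
)

IMPUTABLE_FEATURES = tuple(f for f in FEATURES if f not in CONTEXT_FEATURES)

#: channel whose raw events back each imputable feature (drives the
#: observed/unobserved mask)
FEATURE_CHANNEL = {
    "mean_acceleration": "acceleration",
    "n_unique_apps": "app",
    **{f"n_{s}_calls": "call" for s in CALL_SUBTYPES},
    **{f"{s}_call_duration": "call" for s in CALL_SUBTYPES},
    "n_conversations": "conversation",
    "conversation_duration": "conversation",
    **{f: "gps" for f in LOCATION_FEATURES},
    "distance_travelled": "gps",
    "n_screen_unlocks": "screen",
    "screen_duration": "screen",
    **{f: "sleep" for f in SLEEP_FEATURES},
    **{f"n_{s}_texts": "text" for s in TEXT_SUBTYPES},
}

#: day labels.  The relapse day itself belongs to neither the near-relapse
#: window nor the healthy baseline and is excluded from both.
LABEL_DRH = "DRH"
LABEL_NR30 = "NR30"
LABEL_RELAPSE = "RELAPSE"

N_FEATURES = len(FEATURES)
N_IMPUTABLE = len(IMPUTABLE_FEATURES)


def encode_onset(clock_hours):
    """Map a wall-clock onset hour in [0, 24) onto a continuous axis centred
    on midnight, (-12, 12], so 23:00 becomes -1 and 01:00 stays 1."""
    import numpy as np

    h = np.asarray(clock_hours, dtype=float) % 24.0
    return np.where(h > 12.0, h - 24.0, h)
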