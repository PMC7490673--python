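"""Post hoc interpretation of flagged anomalies.

Per-participant standardized mean differences (Cohen's d, pooled SD) between
hourly feature values on flagged near-relapse days and all healthy days; a
top-5 ranking by |d| with effect classes (large > 0.8, medium 0.5-0.8); an
odds ratio for whole-hour missingness vs anomaly status; and a one-sided
Mann-Whitney U test (exact by enumeration for small samples, midrank normal
approximation with tie correction otherwise).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from math import comb, erf, sqrt

import numpy as np
import pandas as pd

from .schema import CONTEXT_FEATURES, IMPUTABLE_FEATURES, LABEL_DRH, LABEL_NR30


def cohens_d(group_a, group_b) -> float:
    """Classical Cohen's d: (mean_a - mean_b) / pooled SD with (n-1) weights.

    Positive = group_a higher.  NaN when the pooled SD is zero (undefined,
    never +-inf).
    """
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need at least 2 values")
    na, nb = len(a), len(b)
    pooled_var = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if pooled_var <= 0.0:
        return float("nan")
    return float((a.mean() - b.mean()) / sqrt(pooled_var))


def effect_class(d: float) -> str:
    """large: |d| > 0.8; medium: 0.5 < |d| <= 0.8; otherwise below-medium."""
    if np.isnan(d):
        return "undefined"
    a = abs(d)
    if a > 0.8:
        return "large"
    if a > 0.5:
        return "medium"
    return "below-medium"


@dataclass
class EffectSizeReport:
    participant_id: str
    effects: pd.DataFrame             # feature, d, effect_class
    top5: list = field(default_factory=list)
    missingness_or: float = float("nan")
    distributions: dict = field(default_factory=dict)  # feature -> {group: values}


def feature_effect_ranking(
    participant_id: str,
    hourly: pd.DataFrame,
    flagged_days: set,
    day_labels: pd.Series,
    features: tuple = None,
) -> EffectSizeReport:
    """Compare hourly feature values on flagged NR30 days against all DRH days.

    ``hourly``: the participant's dense hourly matrix (columns date + feature
    columns).  ``day_labels``: date -> label.  Sign convention: positive d
    means the feature ran higher on flagged near-relapse days.
    """
    features = tuple(features or (f for f in IMPUTABLE_FEATURES))
    lab = hourly["date"].map(day_labels)
    anom = hourly["date"].isin(flagged_days) & (lab == LABEL_NR30)
    drh = lab == LABEL_DRH
    if not anom.any():
        warnings.warn(f"{participant_id}: no flagged NR30 days; empty report", stacklevel=2)
        return EffectSizeReport(participant_id, pd.DataFrame(columns=["feature", "d", "effect_class"]))
    rows, dists = [], {}
    for f in features:
        if f in CONTEXT_FEATURES:
            continue
        a = hourly.loc[anom, f].to_numpy(float)
        b = hourly.loc[drh, f].to_numpy(float)
        d = cohens_d(a, b) if len(a) >= 2 and len(b) >= 2 else float("nan")
        rows.append({"feature": f, "d": d, "effect_class": effect_class(d)})
        dists[f] = {"nr30_anomaly": a, "drh": b}
    eff = pd.DataFrame(rows)
    ranked = eff.dropna(subset=["d"]).reindex(
        eff.dropna(subset=["d"])["d"].abs().sort_values(ascending=False).index
    )
    top5 = ranked["feature"].head(5).tolist()
    return EffectSizeReport(
        participant_id, effects=eff, top5=top5,
        distributions={f: dists[f] for f in top5},
    )


def missingness_odds_ratio(type2_day_flags, anomaly_day_flags) -> float:
    """Cross-product odds ratio of the 2x2 table (day has >= 1 fully-missing
    hour) x (day flagged as NR30 anomaly), Haldane 0.5 correction when any
    cell is empty."""
    t2 = np.asarray(type2_day_flags, bool)
    an = np.asarray(anomaly_day_flags, bool)
    if t2.shape != an.shape:
        raise ValueError("day flag vectors must align")
    if t2.size == 0:
        raise ValueError("empty table")
    a = float(np.sum(t2 & an))
    b = float(np.sum(t2 & ~an))
    c = float(np.sum(~t2 & an))
    d = float(np.sum(~t2 & ~an))
    if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
        warnings.warn("empty margin in odds-ratio table", stacklevel=2)
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a * d) / (b * c)


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U for group a with midrank tie handling."""
    pooled = np.concatenate([a, b])
    order = pooled.argsort(kind="mergesort")
    ranks = np.empty(len(pooled))
    sorted_vals = pooled[order]
    i = 0
    while i < len(pooled):
        j = i
        while j + 1 < len(pooled) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    r_a = ranks[: len(a)].sum()
    return r_a - len(a) * (len(a) + 1) / 2.0


def mannwhitney_type2(anomaly_counts, other_counts, exact_max_n: int = 16):
    """One-sided Mann-Whitney U for 'anomaly days carry fewer fully-missing
    hours than other days' (alternative: anomaly group stochastically
    smaller).  Exact permutation enumeration when nA + nB <= exact_max_n,
    else midrank normal approximation with tie-corrected variance.

    Returns ``(U, p)`` where U counts pairs favouring the anomaly group.
    """
    a = np.asarray(anomaly_counts, float)
    b = np.asarray(other_counts, float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be nonempty")
    na, nb = len(a), len(b)
    u = _u_statistic(a, b)
    u_other = _u_statistic(b, a)
    assert abs(u + u_other - na * nb) < 1e-9  # the two one-sided U's always pair up
    pooled0 = np.concatenate([a, b])
    if np.all(pooled0 == pooled0[0]):
        return u, 0.5  # no evidence either way
    if na + nb <= exact_max_n:
        pooled = np.concatenate([a, b])
        count = 0
        total = comb(na + nb, na)
        idx_all = set(range(na + nb))
        for pick in combinations(range(na + nb), na):
            ga = pooled[list(pick)]
            gb = pooled[list(idx_all - set(pick))]
            if _u_statistic(ga, gb) <= u + 1e-9:
                count += 1
        return u, count / total
    # normal approximation with tie correction
    pooled = np.concatenate([a, b])
    n = na + nb
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (n * (n - 1))
    var_u = na * nb / 12.0 * ((n + 1) - tie_term)
    if var_u <= 0:
        return u, 0.5
    z = (u + 0.5 - na * nb / 2.0) / sqrt(var_u)  # continuity-corrected, lower tail
    p = 0.5 * (1.0 + erf(z / sqrt(2.0)))
    return u, float(p)
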