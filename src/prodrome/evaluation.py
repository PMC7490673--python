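"""Confusion metrics, Monte Carlo aggregation, model ranking, data-quality
regression and the anomaly-rate-vs-days-to-relapse timeline."""

from __future__ import annotations

import warnings
from datetime import timedelta

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import rankdata

from .schema import LABEL_DRH, LABEL_NR30


def confusion_metrics(flags, labels) -> dict:
    """TPR/FPR/sensitivity/specificity from per-day flags and labels.

    TPR = flagged NR30 days / NR30 days; FPR = flagged DRH days / DRH days.
    Days labelled neither way (the relapse day itself) are ignored.
    """
    flags = np.asarray(flags, bool)
    labels = np.asarray(labels)
    if flags.shape != labels.shape:
        raise ValueError("flags and labels must align")
    nr = labels == LABEL_NR30
    drh = labels == LABEL_DRH
    if not nr.any():
        warnings.warn("no NR30 days: sensitivity undefined", stacklevel=2)
        return {"tpr": np.nan, "fpr": np.nan, "sensitivity": np.nan, "specificity": np.nan}
    tpr = float(flags[nr].mean())
    fpr = float(flags[drh].mean()) if drh.any() else np.nan
    return {"tpr": tpr, "fpr": fpr, "sensitivity": tpr, "specificity": 1.0 - fpr}


def aggregate_monte_carlo(records: pd.DataFrame, nesting: str = "participant_first") -> dict:
    """Summarise per-(iteration, participant) metrics into config-level
    median (IQR) sensitivity and specificity.

    Default nesting: per participant, take the median over iterations first,
    then the median/IQR across participants.
    """
    if records.empty:
        raise ValueError("no records")
    if nesting == "participant_first":
        per_part = records.groupby("participant_id", sort=True)[["sensitivity", "specificity"]].median()
    elif nesting == "pooled":
        per_part = records[["sensitivity", "specificity"]]
    else:
        raise ValueError(f"unknown nesting {nesting!r}")
    out = {}
    for col in ("sensitivity", "specificity"):
        v = per_part[col].dropna().to_numpy(float)
        if v.size == 0:
            out[col] = {"median": np.nan, "q1": np.nan, "q3": np.nan}
        else:
            q1, med, q3 = np.percentile(v, [25, 50, 75])
            out[col] = {"median": float(med), "q1": float(q1), "q3": float(q3)}
    return out


def rank_models(ratios: pd.DataFrame) -> pd.DataFrame:
    """Mean rank per configuration across participants.

    ``ratios``: rows (config, participant_id, ratio).  Within each participant
    configs are ranked by descending TPR/FPR ratio (1 = best, fractional ranks
    on ties); the returned frame (config, mean_rank) is sorted best first.
    """
    if ratios["config"].nunique() < 2:
        raise ValueError("need at least two configurations to rank")
    ranks = []
    for pid, sub in ratios.groupby("participant_id", sort=True):
        r = rankdata(-sub["ratio"].to_numpy(float), method="average")
        ranks.append(pd.DataFrame({"config": sub["config"].to_numpy(), "rank": r}))
    allr = pd.concat(ranks)
    out = allr.groupby("config", sort=True)["rank"].mean().rename("mean_rank").reset_index()
    return out.sort_values("mean_rank", kind="mergesort").reset_index(drop=True)


def data_quality_regression(rows: pd.DataFrame, outcomes=("sensitivity", "specificity")) -> pd.DataFrame:
    """OLS of each z-standardised outcome on the z-standardised data-quality
    predictors; returns standardized beta with 95% CI and p per predictor
    (the intercept of a fully standardized fit is ~0 by construction)."""
    predictors = [c for c in rows.columns if c not in outcomes]
    if len(rows) < len(predictors) + 2:
        raise ValueError("not enough rows for regression")

    def z(v):
        v = np.asarray(v, float)
        sd = v.std(ddof=1)
        return (v - v.mean()) / (sd if sd > 0 else 1.0)

    X = np.column_stack([z(rows[c]) for c in predictors])
    if len(predictors) > 1 and np.linalg.cond(X.T @ X) > 1e8:
        warnings.warn("predictors are nearly collinear", stacklevel=2)
    Xc = sm.add_constant(X)
    out = []
    for outc in outcomes:
        fit = sm.OLS(z(rows[outc]), Xc).fit()
        ci = fit.conf_int(alpha=0.05)
        for i, name in enumerate(["intercept"] + predictors):
            out.append(
                {
                    "outcome": outc,
                    "predictor": name,
                    "beta": float(fit.params[i]),
                    "ci_low": float(ci[i, 0]),
                    "ci_high": float(ci[i, 1]),
                    "p": float(fit.pvalues[i]),
                }
            )
    return pd.DataFrame(out)


def anomaly_rate_timeline(
    flags: pd.DataFrame,
    relapse_dates: dict,
    window: int = 35,
) -> pd.DataFrame:
    """Mean anomaly rate (with normal-approx 95% CI) at each offset of
    1..window days before relapse, averaged across participant-relapse pairs.

    ``flags``: columns participant_id, date, flag (possibly many iterations'
    worth; rates are averaged per participant-date first).
    """
    per_day = flags.groupby(["participant_id", "date"], sort=True)["flag"].mean()
    rows = []
    for k in range(window, 0, -1):
        vals = []
        for pid, rdates in relapse_dates.items():
            for r in rdates:
                key = (pid, r - timedelta(days=k))
                if key in per_day.index:
                    vals.append(float(per_day.loc[key]))
        if not vals:
            rows.append({"days_before": k, "rate": np.nan, "lo": np.nan, "hi": np.nan, "n": 0})
            continue
        v = np.asarray(vals)
        m = float(v.mean())
        se = float(v.std(ddof=1) / np.sqrt(len(v))) if len(v) > 1 else 0.0
        rows.append(
            {
                "days_before": k,
                "rate": m,
                "lo": max(0.0, m - 1.96 * se),
                "hi": min(1.0, m + 1.96 * se),
                "n": len(v),
            }
        )
    return pd.DataFrame(rows)
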