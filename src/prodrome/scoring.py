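"""From reconstructions to anomaly flags.

Hourly absolute reconstruction errors are modelled as Gaussian with mean and
covariance estimated on the healthy validation set; the hourly anomaly score
is the Mahalanobis distance of an error vector from that distribution.  Daily
scores are the mean of the day's retained hourly scores, and a per-participant
threshold, learned on the mixed validation set by maximising TPR/FPR over a
candidate grid in [0, 20], turns daily scores into anomaly flags (strictly
greater-than; a day scoring exactly at the threshold is normal).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from .schema import LABEL_DRH, LABEL_NR30

TAU_RANGE = (0.0, 20.0)


def reconstruction_errors(x: np.ndarray, x_prime: np.ndarray) -> np.ndarray:
    """Elementwise absolute error |x - x'| between aligned (stacks of) vectors."""
    x = np.asarray(x, float)
    x_prime = np.asarray(x_prime, float)
    if x.shape != x_prime.shape:
        raise ValueError(f"shape mismatch {x.shape} vs {x_prime.shape}")
    return np.abs(x - x_prime)


def consolidate_hour_predictions(window_recons: np.ndarray, l: int) -> tuple[np.ndarray, np.ndarray]:
    """Combine stride-1 window reconstructions into per-hour predictions.

    ``window_recons`` has shape (n_windows, l, m) for one contiguous segment
    of L = n_windows + l - 1 hours.  Only hours covered by exactly ``l``
    windows are retained (their ``l`` predictions averaged); returns
    ``(hour_indices, consolidated)`` where indices are 0-based positions in
    the segment.
    """
    wr = np.asarray(window_recons, float)
    if wr.ndim != 3 or wr.shape[1] != l:
        raise ValueError("window_recons must have shape (n_windows, l, m)")
    n_w, _, m = wr.shape
    if n_w == 0:
        return np.empty(0, dtype=int), np.empty((0, m))
    L = n_w + l - 1
    if l == 1:
        return np.arange(L), wr[:, 0, :]
    lo, hi = l - 1, L - l  # inclusive range of fully covered hours
    if hi < lo:
        return np.empty(0, dtype=int), np.empty((0, m))
    idx = np.arange(lo, hi + 1)
    acc = np.zeros((len(idx), m))
    for k in range(l):
        acc += wr[idx - k, k, :]
    return idx, acc / l


@dataclass
class ErrorDistribution:
    mu: np.ndarray
    sigma: np.ndarray
    lam: float          # shrinkage actually applied
    _chol: tuple = None

    def cho(self):
        if self._chol is None:
            self._chol = cho_factor(self.sigma)
        return self._chol


def fit_error_distribution(errors: np.ndarray, lam_scale: float = 1e-6) -> ErrorDistribution:
    """Sample mean/covariance of error vectors with ridge shrinkage
    lam * I, lam raised tenfold until the condition number is < 1e10."""
    E = np.atleast_2d(np.asarray(errors, float))
    if len(E) < 2:
        raise ValueError("need at least 2 error vectors")
    mu = E.mean(axis=0)
    sigma = np.cov(E, rowvar=False, ddof=1)
    sigma = np.atleast_2d(sigma)
    m = sigma.shape[0]
    lam = lam_scale * np.trace(sigma) / m
    if lam <= 0 or not np.isfinite(lam):
        lam = lam_scale
    while True:
        reg = sigma + lam * np.eye(m)
        if np.linalg.cond(reg) < 1e10:
            break
        lam *= 10.0
    return ErrorDistribution(mu=mu, sigma=sigma + lam * np.eye(m), lam=lam)


def mahalanobis_score(e: np.ndarray, dist: ErrorDistribution) -> np.ndarray:
    """sqrt((e - mu)^T Sigma^-1 (e - mu)); vectorised over rows of ``e``."""
    e = np.asarray(e, float)
    if not np.all(np.isfinite(e)):
        raise ValueError("non-finite error vector")
    single = e.ndim == 1
    E = np.atleast_2d(e) - dist.mu
    solved = cho_solve(dist.cho(), E.T).T
    s = np.sqrt(np.maximum(np.einsum("ij,ij->i", E, solved), 0.0))
    return float(s[0]) if single else s


def daily_scores(hourly: pd.DataFrame) -> pd.DataFrame:
    """Average hourly scores into daily scores.

    ``hourly`` needs columns participant_id, date, score.  Days with zero
    retained hours simply do not appear.  Returns columns participant_id,
    date, s_d, n_hours.
    """
    g = hourly.groupby(["participant_id", "date"], sort=True)["score"]
    out = g.agg(s_d="mean", n_hours="size").reset_index()
    return out


def _confusion(scores, labels, tau):
    nr = labels == LABEL_NR30
    drh = labels == LABEL_DRH
    flagged = scores > tau
    tpr = flagged[nr].mean() if nr.any() else np.nan
    fpr = flagged[drh].mean() if drh.any() else 0.0
    return tpr, fpr


def learn_threshold(
    daily: pd.DataFrame,
    tau_range: tuple = TAU_RANGE,
) -> pd.DataFrame:
    """Per-participant threshold maximising TPR/FPR on daily scores.

    ``daily`` needs columns participant_id, s_d, label.  The candidate grid is
    every observed score (clipped into the search range) plus midpoints and
    the range ends; an FPR of zero is floored at 1/(#DRH days + 1) so perfect
    separation wins but stays finite; argmax ties break toward the largest
    threshold (fewest anomalies).  Returns one row per participant:
    participant_id, tau, ratio, degenerate.
    """
    lo, hi = tau_range
    rows = []
    for pid, sub in daily.groupby("participant_id", sort=True):
        labels = sub["label"].to_numpy()
        scores = sub["s_d"].to_numpy(float)
        n_nr = int((labels == LABEL_NR30).sum())
        n_drh = int((labels == LABEL_DRH).sum())
        if n_nr == 0 or n_drh == 0:
            warnings.warn(f"{pid}: no NR30 (or no DRH) days in N_CV; excluded", stacklevel=2)
            continue
        uniq = np.unique(np.clip(scores, lo, hi))
        cand = np.concatenate([[lo], uniq, (uniq[:-1] + uniq[1:]) / 2.0, [hi]])
        cand = np.unique(cand)
        floor = 1.0 / (n_drh + 1)
        best_tau, best_ratio = lo, -np.inf
        for tau in cand:  # ascending: >= keeps the largest tie
            tpr, fpr = _confusion(scores, labels, tau)
            ratio = tpr / max(fpr, floor)
            if ratio >= best_ratio - 1e-12:
                best_tau, best_ratio = float(tau), float(max(ratio, best_ratio))
        tpr, _ = _confusion(scores, labels, best_tau)
        # no threshold separates anomalies from baseline at all
        degenerate = bool(tpr == 0.0 or best_ratio <= 1.0 + 1e-12)
        rows.append(
            {
                "participant_id": pid,
                "tau": best_tau,
                "ratio": best_ratio,
                "degenerate": degenerate,
            }
        )
    return pd.DataFrame(rows, columns=["participant_id", "tau", "ratio", "degenerate"])


def flag_anomalies(daily: pd.DataFrame, taus: pd.DataFrame) -> pd.DataFrame:
    """Apply per-participant thresholds learned elsewhere: flag = (s_d > tau),
    strict inequality, never re-optimised on the evaluated set."""
    tau_map = taus.set_index("participant_id")["tau"]
    out = daily.copy()
    out["tau"] = out["participant_id"].map(tau_map)
    out = out[out["tau"].notna()].copy()
    out["flag"] = out["s_d"].to_numpy(float) > out["tau"].to_numpy(float)
    return out
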