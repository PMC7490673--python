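"""Local-outlier-factor baseline with a neighbour-convergence loop.

A per-participant novelty LOF is fitted on that participant's healthy
training hours, starting at 10 neighbours and incrementing by one until the
mean and SD of the validation scores stop moving (relative change below
tolerance in both), capped at a configurable maximum.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.neighbors import LocalOutlierFactor


def lof_scores(model: LocalOutlierFactor, X: np.ndarray) -> np.ndarray:
    """Positive LOF scores (~1 for inliers, larger = more outlying), shape
    (n, 1) so they flow through the same error-vector scoring machinery."""
    return (-model.score_samples(np.asarray(X, float))).reshape(-1, 1)


def fit_lof(
    h_r: np.ndarray,
    h_cv: np.ndarray,
    n_neighbors_start: int = 10,
    tol: float = 1e-3,
    cap: int = 100,
):
    """Returns ``(model, n_neighbors, history)`` where history rows are
    (k, mean, sd) of the validation scores."""
    h_r = np.asarray(h_r, float)
    h_cv = np.asarray(h_cv, float)
    if len(h_r) < n_neighbors_start + 1:
        raise ValueError("need at least n_neighbors_start + 1 training hours")
    history = []
    prev = None
    model = None
    k = n_neighbors_start
    while k <= min(cap, len(h_r) - 1):
        model = LocalOutlierFactor(n_neighbors=k, novelty=True)
        model.fit(h_r)
        s = lof_scores(model, h_cv)
        cur = (float(s.mean()), float(s.std()))
        history.append((k, *cur))
        if prev is not None:
            dm = abs(cur[0] - prev[0]) / max(abs(prev[0]), 1e-12)
            ds = abs(cur[1] - prev[1]) / max(abs(prev[1]), 1e-12)
            if dm < tol and ds < tol:
                return model, k, history
        prev = cur
        k += 1
    warnings.warn("LOF neighbour-convergence loop hit the cap; using the cap", stacklevel=2)
    return model, k - 1, history
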