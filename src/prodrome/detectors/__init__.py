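"""Reconstruction models: FNN autoencoder, GRU seq2seq and the LOF baseline.

One global neural model per configuration is trained on pooled healthy
training hours (H_R); features are z-scored with statistics from H_R only and
those statistics are reused unchanged everywhere downstream.  Training uses
Adam with early stopping on the H_CV reconstruction loss (patience in epochs,
best-epoch checkpoint restored).  The LOF baseline is per-participant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .autodiff import Adam, Parameter, Tensor
from .fnn import FNNAutoencoder
from .gru import GRUSeq2Seq, segment_windows
from .lof import fit_lof, lof_scores

__all__ = [
    "Scaler",
    "ReconstructionModel",
    "train_fnn_ad",
    "train_gru_seq2seq",
    "train_lof",
    "reconstruct",
    "fit_lof",
    "lof_scores",
    "FNNAutoencoder",
    "GRUSeq2Seq",
    "segment_windows",
]


@dataclass
class Scaler:
    mean: np.ndarray
    std: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "Scaler":
        X = np.asarray(X, float)
        std = X.std(axis=0)
        return cls(mean=X.mean(axis=0), std=np.where(std < 1e-8, 1.0, std))

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, float) - self.mean) / self.std


@dataclass
class ReconstructionModel:
    arch: str                      # fnn_ad | gru_seq2seq | lof
    model: object
    scaler: Scaler
    hidden_units: int
    seed: int
    window: int = 1
    history: list = field(default_factory=list)  # (train_loss, val_loss) per epoch
    extras: dict = field(default_factory=dict)


def _snapshot(params):
    return [p.data.copy() for p in params]


def _restore(params, snap):
    for p, s in zip(params, snap):
        p.data = s.copy()


def _train(
    params,
    run_epoch,
    val_loss,
    max_epochs: int,
    patience: int,
    lr: float,
):
    """Generic early-stopped optimisation; returns history and restores the
    parameters of the best-validation epoch."""
    opt = Adam(params, lr=lr)
    best = _snapshot(params)
    best_val = val_loss()
    bad = 0
    history = []
    for _ in range(max_epochs):
        tr = run_epoch(opt)
        vl = val_loss()
        history.append((tr, vl))
        if vl < best_val - 1e-10:
            best_val = vl
            best = _snapshot(params)
            bad = 0
        else:
            bad += 1
            if bad >= patience:
                break
    _restore(params, best)
    return history, best_val


def train_fnn_ad(
    h_r: np.ndarray,
    h_cv: np.ndarray,
    hidden_units: int,
    seed: int = 0,
    lr: float = 2e-3,
    max_epochs: int = 200,
    patience: int = 5,
    batch_size: int = 256,
) -> ReconstructionModel:
    """Train the fully connected autoencoder on pooled healthy hours."""
    h_r = np.asarray(h_r, float)
    h_cv = np.asarray(h_cv, float)
    m = h_r.shape[1]
    if hidden_units >= m:
        warnings.warn(f"hidden_units={hidden_units} >= {m} features: no compression", stacklevel=2)
    scaler = Scaler.fit(h_r)
    Xtr = scaler.transform(h_r)
    Xcv = scaler.transform(h_cv)
    rng = np.random.default_rng(seed)
    net = FNNAutoencoder(m, hidden_units, seed=seed)

    def run_epoch(opt):
        order = rng.permutation(len(Xtr))
        losses = []
        for start in range(0, len(order), batch_size):
            batch = Xtr[order[start : start + batch_size]]
            opt.zero_grad()
            loss = net.loss(batch)
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        return float(np.mean(losses))

    def val_loss():
        return float(net.loss(Xcv).data)

    history, _ = _train(net.params, run_epoch, val_loss, max_epochs, patience, lr)
    return ReconstructionModel(
        arch="fnn_ad", model=net, scaler=scaler, hidden_units=hidden_units,
        seed=seed, window=1, history=history,
    )


def train_gru_seq2seq(
    h_r_segments: list,
    h_cv_segments: list,
    hidden_units: int,
    seed: int = 0,
    window: int = 24,
    lr: float = 2e-3,
    max_epochs: int = 60,
    patience: int = 5,
    batch_size: int = 64,
    feed_next_pred: bool = True,
) -> ReconstructionModel:
    """Train the GRU seq2seq on stride-1 windows drawn within contiguous
    same-split segments only (no window straddles a block boundary)."""
    scaler = Scaler.fit(np.concatenate([np.asarray(s, float) for s in h_r_segments]))
    Wtr = _segments_to_windows(h_r_segments, scaler, window)
    Wcv = _segments_to_windows(h_cv_segments, scaler, window)
    if len(Wtr) == 0 or len(Wcv) == 0:
        raise ValueError("no full windows available; segments shorter than the window")
    m = Wtr.shape[2]
    rng = np.random.default_rng(seed)
    net = GRUSeq2Seq(m, hidden_units, window=window, feed_next_pred=feed_next_pred, seed=seed)

    def run_epoch(opt):
        order = rng.permutation(len(Wtr))
        losses = []
        for start in range(0, len(order), batch_size):
            batch = Wtr[order[start : start + batch_size]]
            opt.zero_grad()
            loss = net.loss(batch, train=True, rng=rng)
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        return float(np.mean(losses))

    def val_loss():
        tot, n = 0.0, 0
        for start in range(0, len(Wcv), 256):
            batch = Wcv[start : start + 256]
            tot += float(net.loss(batch, train=False).data) * len(batch)
            n += len(batch)
        return tot / n

    history, _ = _train(net.params, run_epoch, val_loss, max_epochs, patience, lr)
    return ReconstructionModel(
        arch="gru_seq2seq", model=net, scaler=scaler, hidden_units=hidden_units,
        seed=seed, window=window, history=history,
    )


def _segments_to_windows(segments, scaler, window):
    parts = [
        segment_windows(scaler.transform(np.asarray(s, float)), window)
        for s in segments
    ]
    parts = [p for p in parts if len(p)]
    if not parts:
        m = len(scaler.mean)
        return np.empty((0, window, m))
    return np.concatenate(parts)


def train_lof(h_r: np.ndarray, h_cv: np.ndarray, seed: int = 0, **kw) -> ReconstructionModel:
    """Per-participant LOF baseline (callers fit one per relapse participant)."""
    scaler = Scaler.fit(np.asarray(h_r, float))
    model, k, history = fit_lof(scaler.transform(h_r), scaler.transform(h_cv), **kw)
    return ReconstructionModel(
        arch="lof", model=model, scaler=scaler, hidden_units=0, seed=seed,
        window=1, history=history, extras={"n_neighbors": k},
    )


def reconstruct(model: ReconstructionModel, data):
    """Deterministic inference.

    fnn_ad: ``data`` is an (n, m) raw matrix -> (X_std, recon_std).
    gru_seq2seq: ``data`` is one contiguous raw segment -> (X_std, window
    reconstructions of shape (n_windows, l, m)).
    lof: ``data`` is an (n, m) raw matrix -> (n, 1) LOF scores, which play
    the role of a 1-dim error stream downstream.
    """
    if model.arch == "fnn_ad":
        X = model.scaler.transform(np.asarray(data, float))
        if X.shape[1] != model.model.n_features:
            raise ValueError("feature-dimension mismatch")
        return X, model.model.reconstruct(X)
    if model.arch == "gru_seq2seq":
        X = model.scaler.transform(np.asarray(data, float))
        if X.shape[1] != model.model.n_features:
            raise ValueError("feature-dimension mismatch")
        return X, model.model.reconstruct_windows(segment_windows(X, model.window))
    if model.arch == "lof":
        X = model.scaler.transform(np.asarray(data, float))
        return lof_scores(model.model, X)
    raise ValueError(f"unknown architecture {model.arch!r}")
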