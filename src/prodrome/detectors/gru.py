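"""Bidirectional-GRU sequence-to-sequence reconstruction model.

The encoder runs a forward and a backward GRU over a 24-hour window; the
final states are concatenated into a summary state from which a dense head
predicts the next timestep.  A unidirectional GRU decoder is seeded with the
summary state (and, by default, the next-step prediction as its first input
token) and emits the window *in reverse order*: decoder step j reconstructs
input step l-1-j.  Dropout 0.2 and recurrent dropout 0.2 apply during
training only.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor
from .layers import Dense, GRUCell, dropout_mask


class GRUSeq2Seq:
    def __init__(
        self,
        n_features: int,
        hidden_units: int,
        window: int = 24,
        dropout: float = 0.2,
        recurrent_dropout: float = 0.2,
        feed_next_pred: bool = True,
        seed: int = 0,
    ):
        rng = np.random.default_rng(seed)
        self.n_features = n_features
        self.hidden_units = hidden_units
        self.window = window
        self.dropout = dropout
        self.recurrent_dropout = recurrent_dropout
        self.feed_next_pred = feed_next_pred
        self.enc_fwd = GRUCell(rng, n_features, hidden_units)
        self.enc_bwd = GRUCell(rng, n_features, hidden_units)
        self.next_head = Dense(rng, 2 * hidden_units, n_features)
        self.decoder = GRUCell(rng, n_features, 2 * hidden_units)
        self.out_head = Dense(rng, 2 * hidden_units, n_features)

    @property
    def params(self):
        return (
            self.enc_fwd.params
            + self.enc_bwd.params
            + self.next_head.params
            + self.decoder.params
            + self.out_head.params
        )

    def _forward(self, W: np.ndarray, train: bool, rng) -> list[Tensor]:
        """Returns the decoder outputs in emission (reversed) order."""
        B, l, m = W.shape
        if l != self.window:
            raise ValueError(f"window length {l} != model window {self.window}")
        if m != self.n_features:
            raise ValueError("feature dimension mismatch")
        in_mask = rec_mask_f = rec_mask_b = rec_mask_d = None
        if train and rng is not None:
            in_mask = dropout_mask(rng, (B, m), self.dropout)
            rec_mask_f = dropout_mask(rng, (B, self.hidden_units), self.recurrent_dropout)
            rec_mask_b = dropout_mask(rng, (B, self.hidden_units), self.recurrent_dropout)
            rec_mask_d = dropout_mask(rng, (B, 2 * self.hidden_units), self.recurrent_dropout)

        def inp(t):
            x = Tensor(W[:, t, :])
            return x * in_mask if in_mask is not None else x

        hf = Tensor(np.zeros((B, self.hidden_units)))
        for t in range(l):
            hf = self.enc_fwd.step(inp(t), hf, rec_mask_f)
        hb = Tensor(np.zeros((B, self.hidden_units)))
        for t in reversed(range(l)):
            hb = self.enc_bwd.step(inp(t), hb, rec_mask_b)

        h = Tensor.concat([hf, hb], axis=-1)  # summary state
        x_next = self.next_head(h)            # next-timestep prediction
        out = []
        token = x_next if self.feed_next_pred else Tensor(np.zeros((B, m)))
        for _ in range(l):
            h = self.decoder.step(token, h, rec_mask_d)
            y = self.out_head(h)
            out.append(y)
            token = y
        return out

    def loss(self, W: np.ndarray, train: bool = True, rng=None) -> Tensor:
        out = self._forward(W, train, rng)
        l = len(out)
        total = None
        for j, y in enumerate(out):
            diff = y - Tensor(W[:, l - 1 - j, :])
            sq = (diff * diff).mean()
            total = sq if total is None else total + sq
        return total / l

    def reconstruct_windows(self, W: np.ndarray) -> np.ndarray:
        """Deterministic inference: reconstructions re-aligned to input order,
        shape (n_windows, l, m)."""
        out = self._forward(W, train=False, rng=None)
        stacked = np.stack([y.data for y in out], axis=1)
        return stacked[:, ::-1, :]

    def reconstruct_reversed(self, W: np.ndarray) -> np.ndarray:
        """Raw decoder emission order {x'(l), ..., x'(1)} for contract tests."""
        out = self._forward(W, train=False, rng=None)
        return np.stack([y.data for y in out], axis=1)


def segment_windows(segment: np.ndarray, l: int) -> np.ndarray:
    """Stride-1 windows of length ``l`` within one contiguous segment; windows
    never straddle segment boundaries.  Shape (L-l+1, l, m); empty if L < l."""
    L, m = segment.shape
    if L < l:
        return np.empty((0, l, m))
    idx = np.arange(L - l + 1)[:, None] + np.arange(l)[None, :]
    return segment[idx]
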