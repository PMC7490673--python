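"""Fully connected autoencoder over single hourly feature vectors (window
length 1): a two-layer encoder compressing to the hidden width and a
mirrored two-layer decoder."""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor
from .layers import Dense, mse


class FNNAutoencoder:
    def __init__(self, n_features: int, hidden_units: int, seed: int = 0):
        rng = np.random.default_rng(seed)
        mid = max(hidden_units, (n_features + hidden_units) // 2)
        self.n_features = n_features
        self.hidden_units = hidden_units
        self.enc1 = Dense(rng, n_features, mid, activation="relu")
        self.enc2 = Dense(rng, mid, hidden_units, activation=None)
        self.dec1 = Dense(rng, hidden_units, mid, activation="relu")
        self.dec2 = Dense(rng, mid, n_features, activation=None)

    @property
    def params(self):
        return self.enc1.params + self.enc2.params + self.dec1.params + self.dec2.params

    def forward(self, X: np.ndarray) -> Tensor:
        return self.dec2(self.dec1(self.enc2(self.enc1(Tensor(X)))))

    def loss(self, X: np.ndarray) -> Tensor:
        return mse(self.forward(X), X)

    def reconstruct(self, X: np.ndarray) -> np.ndarray:
        """Deterministic inference pass."""
        return self.forward(X).data
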