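"""Dense and gated-recurrent building blocks on top of the autodiff core."""

from __future__ import annotations

import numpy as np

from .autodiff import Parameter, Tensor


def glorot(rng, fan_in, fan_out):
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-lim, lim, (fan_in, fan_out))


class Dense:
    def __init__(self, rng, n_in, n_out, activation=None):
        self.W = Parameter(glorot(rng, n_in, n_out))
        self.b = Parameter(np.zeros(n_out))
        self.activation = activation

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.W + self.b
        if self.activation == "tanh":
            out = out.tanh()
        elif self.activation == "relu":
            out = out.relu()
        elif self.activation == "sigmoid":
            out = out.sigmoid()
        elif self.activation is not None:
            raise ValueError(f"unknown activation {self.activation!r}")
        return out

    @property
    def params(self):
        return [self.W, self.b]


class GRUCell:
    """Standard gated recurrent unit: z/r gates plus candidate state."""

    def __init__(self, rng, n_in, n_hidden):
        self.n_hidden = n_hidden
        self.Wz = Parameter(glorot(rng, n_in, n_hidden))
        self.Uz = Parameter(glorot(rng, n_hidden, n_hidden))
        self.bz = Parameter(np.zeros(n_hidden))
        self.Wr = Parameter(glorot(rng, n_in, n_hidden))
        self.Ur = Parameter(glorot(rng, n_hidden, n_hidden))
        self.br = Parameter(np.zeros(n_hidden))
        self.Wh = Parameter(glorot(rng, n_in, n_hidden))
        self.Uh = Parameter(glorot(rng, n_hidden, n_hidden))
        self.bh = Parameter(np.zeros(n_hidden))

    def step(self, x: Tensor, h: Tensor, rec_mask=None) -> Tensor:
        """One timestep.  ``rec_mask`` is a recurrent-dropout mask applied to
        the hidden state entering the gates (same mask every step)."""
        hg = h * rec_mask if rec_mask is not None else h
        z = (x @ self.Wz + hg @ self.Uz + self.bz).sigmoid()
        r = (x @ self.Wr + hg @ self.Ur + self.br).sigmoid()
        htil = (x @ self.Wh + (r * hg) @ self.Uh + self.bh).tanh()
        one = Tensor(np.ones(1))
        return (one - z) * h + z * htil

    @property
    def params(self):
        return [
            self.Wz, self.Uz, self.bz,
            self.Wr, self.Ur, self.br,
            self.Wh, self.Uh, self.bh,
        ]


def dropout_mask(rng, shape, rate):
    """Inverted-dropout mask (scaled so expectations match at inference)."""
    if rate <= 0.0:
        return None
    keep = rng.random(shape) >= rate
    return keep / (1.0 - rate)


def mse(pred: Tensor, target: np.ndarray) -> Tensor:
    diff = pred - Tensor(target)
    return (diff * diff).mean()
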