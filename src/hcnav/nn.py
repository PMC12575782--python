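"""Minimal dense / gated-recurrent network primitives with hand-derived
gradients.

The value networks in this package are small (tens of units), trained
online with batch size 1, so a full autodiff framework would be overkill;
instead the forward and backward passes are written out explicitly and
accelerated with numba.  Gate equations follow the standard GRU
formulation

    r_t = sigmoid(W_r x_t + U_r h_{t-1} + b_ir + b_hr)
    z_t = sigmoid(W_z x_t + U_z h_{t-1} + b_iz + b_hz)
    n_t = tanh(W_n x_t + b_in + r_t * (U_n h_{t-1} + b_hn))
    h_t = (1 - z_t) * n_t + z_t * h_{t-1}

with the three gates stacked row-wise in ``Wx`` (3H x D), ``Uh`` (3H x H),
``bi`` and ``bh`` (3H).  All gradients are checked against central finite
differences in the test suite.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def gru_forward(Wx, Uh, bi, bh, X, h0):
    """Run the GRU over a sequence.

    Returns hidden states ``Hs`` with ``Hs[0] = h0`` and ``Hs[t+1]`` the
    state after consuming ``X[t]``, plus the per-step gate caches needed by
    :func:`gru_backward`.
    """
    T = X.shape[0]
    H = h0.shape[0]
    Hs = np.empty((T + 1, H))
    R = np.empty((T, H))
    Z = np.empty((T, H))
    Nc = np.empty((T, H))
    HH = np.empty((T, H))
    Hs[0] = h0
    GX = X @ Wx.T + bi          # input projections for all steps at once
    for t in range(T):
        gx = GX[t]
        gh = Uh @ Hs[t]
        r = 1.0 / (1.0 + np.exp(-(gx[:H] + gh[:H] + bh[:H])))
        z = 1.0 / (1.0 + np.exp(-(gx[H:2 * H] + gh[H:2 * H] + bh[H:2 * H])))
        hh = gh[2 * H:] + bh[2 * H:]
        n = np.tanh(gx[2 * H:] + r * hh)
        Hs[t + 1] = (1.0 - z) * n + z * Hs[t]
        R[t] = r
        Z[t] = z
        Nc[t] = n
        HH[t] = hh
    return Hs, R, Z, Nc, HH


@njit(cache=True)
def gru_backward(Wx, Uh, X, Hs, R, Z, Nc, HH, dH_inject):
    """Backpropagate through time.

    ``dH_inject[t]`` is the loss gradient arriving directly at ``Hs[t+1]``
    (e.g. from a Q-value readout at step t).  Returns gradients for the
    four GRU parameter blocks.  The time loop only carries the small
    per-step vector algebra; weight-gradient accumulation is deferred to
    two matrix products over the whole sequence.
    """
    T, H = dH_inject.shape
    dG = np.empty((T, 3 * H))       # per-step gate deltas [dar, dz, dan]
    dGh = np.empty((T, 3 * H))      # hidden-side deltas  [dar, dz, dhh]
    dh = np.zeros(H)
    for t in range(T - 1, -1, -1):
        dh = dh + dH_inject[t]
        r = R[t]
        z = Z[t]
        n = Nc[t]
        dz = dh * (Hs[t] - n) * z * (1.0 - z)
        dan = dh * (1.0 - z) * (1.0 - n * n)
        dar = dan * HH[t] * r * (1.0 - r)
        dhh = dan * r
        dG[t, :H] = dar
        dG[t, H:2 * H] = dz
        dG[t, 2 * H:] = dan
        dGh[t, :H] = dar
        dGh[t, H:2 * H] = dz
        dGh[t, 2 * H:] = dhh
        dh = (dh * z + dar @ Uh[:H] + dz @ Uh[H:2 * H] + dhh @ Uh[2 * H:])
    dWx = dG.T @ X
    dUh = dGh.T @ Hs[:T]
    dbi = dG.sum(axis=0)
    dbh = dGh.sum(axis=0)
    return dWx, dUh, dbi, dbh


@njit(cache=True)
def gru_step(Wx, Uh, bi, bh, x, h):
    """Single GRU step (used for online acting and the target network)."""
    H = h.shape[0]
    gx = Wx @ x + bi
    gh = Uh @ h
    r = 1.0 / (1.0 + np.exp(-(gx[:H] + gh[:H] + bh[:H])))
    z = 1.0 / (1.0 + np.exp(-(gx[H:2 * H] + gh[H:2 * H] + bh[H:2 * H])))
    n = np.tanh(gx[2 * H:] + r * (gh[2 * H:] + bh[2 * H:]))
    return (1.0 - z) * n + z * h


def relu(x):
    return np.maximum(x, 0.0)


class Adam:
    """Adam on a flat parameter vector (beta1=0.9, beta2=0.999)."""

    def __init__(self, n_params: int, lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.m = np.zeros(n_params)
        self.v = np.zeros(n_params)
        self.t = 0

    def step(self, theta: np.ndarray, grad: np.ndarray) -> None:
        self.t += 1
        self.m = self.beta1 * self.m + (1.0 - self.beta1) * grad
        self.v = self.beta2 * self.v + (1.0 - self.beta2) * grad * grad
        mhat = self.m / (1.0 - self.beta1 ** self.t)
        vhat = self.v / (1.0 - self.beta2 ** self.t)
        theta -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def state_dict(self):
        return {"m": self.m.copy(), "v": self.v.copy(), "t": self.t}

    def load_state_dict(self, d):
        self.m = d["m"].copy()
        self.v = d["v"].copy()
        self.t = int(d["t"])
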