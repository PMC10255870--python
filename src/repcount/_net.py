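"""Numerical kernels for the counting network.

The network is tiny (a few thousand parameters), so the forward and
backward passes are written directly: the per-timestep dense layers are
vectorized numpy, and the recurrent LSTM loops are numba-jitted.  Padded
batches carry an explicit length vector; the recurrent loops never read
past a sequence's length, which makes padded processing exactly
equivalent to per-sequence processing.

Gate layout in the fused weight matrices is ``[input, forget, cell,
output]`` blocks of size H.  The cell candidate and the cell-to-hidden
activation are linear (the hidden state is ``o * c``); the three gates
are logistic.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def lstm_forward(X2, lengths, Wx, Wh, b, cell_clip):
    """Run the LSTM over a padded batch.

    Parameters
    ----------
    X2 : (B, L, D) float64
        Padded inputs (outputs of the dense stack).
    lengths : (B,) int64
        Valid length of each sequence; steps beyond it are untouched.
    Wx : (D, 4H), Wh : (H, 4H), b : (4H,)

    Returns
    -------
    Hs, Cs : (B, L, H) hidden and cell states (zero in the padding).
    G : (B, L, 4H) activated gate values, cached for the backward pass.
    """
    B, L, D = X2.shape
    H = Wh.shape[0]
    G = np.zeros((B, L, 4 * H))
    Cs = np.zeros((B, L, H))
    Hs = np.zeros((B, L, H))
    for s in range(B):
        hprev = np.zeros(H)
        cprev = np.zeros(H)
        for t in range(lengths[s]):
            pre = np.dot(X2[s, t], Wx) + np.dot(hprev, Wh) + b
            for j in range(H):
                gi = 1.0 / (1.0 + np.exp(-pre[j]))
                gf = 1.0 / (1.0 + np.exp(-pre[H + j]))
                gg = pre[2 * H + j]
                go = 1.0 / (1.0 + np.exp(-pre[3 * H + j]))
                c = gf * cprev[j] + gi * gg
                # linear cell activation leaves the candidate feedback loop
                # unbounded; clip the cell state to keep it stable
                if c > cell_clip:
                    c = cell_clip
                elif c < -cell_clip:
                    c = -cell_clip
                G[s, t, j] = gi
                G[s, t, H + j] = gf
                G[s, t, 2 * H + j] = gg
                G[s, t, 3 * H + j] = go
                Cs[s, t, j] = c
                Hs[s, t, j] = go * c
            hprev = Hs[s, t].copy()
            cprev = Cs[s, t].copy()
    return Hs, Cs, G


@njit(cache=True)
def lstm_backward(X2, lengths, Wx, Wh, Hs, Cs, G, dH, cell_clip):
    """Backpropagate through time; returns (dX2, dWx, dWh, db)."""
    B, L, D = X2.shape
    H = Wh.shape[0]
    dX2 = np.zeros_like(X2)
    dWx = np.zeros_like(Wx)
    dWh = np.zeros_like(Wh)
    db = np.zeros(4 * H)
    for s in range(B):
        dh_rec = np.zeros(H)  # gradient flowing into h_t from step t+1
        dc_rec = np.zeros(H)
        for t in range(lengths[s] - 1, -1, -1):
            dpre = np.zeros(4 * H)
            for j in range(H):
                dh = dH[s, t, j] + dh_rec[j]
                gi = G[s, t, j]
                gf = G[s, t, H + j]
                gg = G[s, t, 2 * H + j]
                go = G[s, t, 3 * H + j]
                c = Cs[s, t, j]
                cprev = Cs[s, t - 1, j] if t > 0 else 0.0
                do = dh * c
                dc = dh * go + dc_rec[j]
                if c >= cell_clip or c <= -cell_clip:
                    dc = 0.0  # saturated cell: no gradient through the clip
                dc_rec[j] = dc * gf
                dpre[j] = dc * gg * gi * (1.0 - gi)
                dpre[H + j] = dc * cprev * gf * (1.0 - gf)
                dpre[2 * H + j] = dc * gi
                dpre[3 * H + j] = do * go * (1.0 - go)
            x = X2[s, t]
            for d in range(D):
                xd = x[d]
                acc = 0.0
                for q in range(4 * H):
                    dWx[d, q] += xd * dpre[q]
                    acc += dpre[q] * Wx[d, q]
                dX2[s, t, d] = acc
            if t > 0:
                for j in range(H):
                    acc = 0.0
                    for q in range(4 * H):
                        dWh[j, q] += Hs[s, t - 1, j] * dpre[q]
                        acc += dpre[q] * Wh[j, q]
                    dh_rec[j] = acc
            else:
                for j in range(H):
                    dh_rec[j] = 0.0
            for q in range(4 * H):
                db[q] += dpre[q]
    return dX2, dWx, dWh, db


def glorot_uniform(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def init_params(
    rng: np.random.Generator, n_channels: int, d1: int, d2: int, h: int
) -> dict[str, np.ndarray]:
    """Seeded parameter initialization.

    Weights are Glorot-uniform.  Gate biases start the recurrence as a
    leaky integrator (damped input gate, slow forget gate, open output
    gate): with random near-zero weights the step signal would be white
    ripple, and the first threshold crossings of a rippled signal
    produce hundreds of spurious count regions from which training does
    not recover.  The integrator start makes the initial signal a smooth
    envelope of the per-step features instead.
    """
    params = {
        "W1": glorot_uniform(rng, n_channels, d1, (n_channels, d1)),
        "b1": np.zeros(d1),
        "W2": glorot_uniform(rng, d1, d2, (d1, d2)),
        "b2": np.zeros(d2),
        "Wx": glorot_uniform(rng, d2, 4 * h, (d2, 4 * h)),
        "Wh": glorot_uniform(rng, h, 4 * h, (h, 4 * h)),
        "b": np.zeros(4 * h),
    }
    params["b"][0:h] = -1.0       # input gate: damped drive
    params["b"][h : 2 * h] = 2.5  # forget gate: slow decay (integrator)
    params["b"][3 * h : 4 * h] = 1.0  # output gate: open
    if h > 1:
        params["Wv"] = glorot_uniform(rng, h, 1, (h,))
        params["bv"] = np.zeros(1)
    return params


def clip_grads(grads: dict[str, np.ndarray], max_norm: float) -> None:
    """Global-norm gradient clipping, in place."""
    total = np.sqrt(sum(float((g * g).sum()) for g in grads.values()))
    if total > max_norm:
        scale = max_norm / total
        for k in grads:
            grads[k] = grads[k] * scale


def zero_like_params(params: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    return {k: np.zeros_like(v) for k, v in params.items()}


def n_parameters(params: dict[str, np.ndarray]) -> int:
    return int(sum(v.size for v in params.values()))


def pad_batch(X: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Stack ragged sequences into a zero-padded (B, Lmax, C) array."""
    lengths = np.array([x.shape[0] for x in X], dtype=np.int64)
    B = len(X)
    C = X[0].shape[1]
    Xpad = np.zeros((B, int(lengths.max()), C))
    for i, x in enumerate(X):
        Xpad[i, : x.shape[0]] = x
    return Xpad, lengths


def forward(params: dict, Xpad: np.ndarray, lengths: np.ndarray, cell_clip: float = 5.0):
    """Full forward pass; returns per-step signals (B, L) and caches."""
    Z1 = Xpad @ params["W1"] + params["b1"]  # linear
    Z2 = Z1 @ params["W2"] + params["b2"]
    A2 = np.maximum(Z2, 0.0)
    Hs, Cs, G = lstm_forward(
        np.ascontiguousarray(A2), lengths, params["Wx"], params["Wh"], params["b"], cell_clip
    )
    if "Wv" in params:
        signal = Hs @ params["Wv"] + params["bv"][0]
    else:
        signal = Hs[:, :, 0]
    cache = (Xpad, lengths, Z1, Z2, A2, Hs, Cs, G, cell_clip)
    return signal, cache


def backward(params: dict, cache, dsignal: np.ndarray) -> dict[str, np.ndarray]:
    """Gradients of a scalar loss w.r.t. all parameters, given d(loss)/d(signal)."""
    Xpad, lengths, Z1, Z2, A2, Hs, Cs, G, cell_clip = cache
    grads: dict[str, np.ndarray] = {}
    if "Wv" in params:
        dH = dsignal[:, :, None] * params["Wv"][None, None, :]
        grads["Wv"] = np.einsum("blh,bl->h", Hs, dsignal)
        grads["bv"] = np.array([dsignal.sum()])
    else:
        dH = dsignal[:, :, None]
    dX2, dWx, dWh, db = lstm_backward(
        np.ascontiguousarray(A2), lengths, params["Wx"], params["Wh"], Hs, Cs, G,
        np.ascontiguousarray(dH), cell_clip,
    )
    grads["Wx"], grads["Wh"], grads["b"] = dWx, dWh, db
    dZ2 = dX2 * (Z2 > 0.0)
    grads["W2"] = np.einsum("bld,blk->dk", Z1, dZ2)
    grads["b2"] = dZ2.sum(axis=(0, 1))
    dZ1 = dZ2 @ params["W2"].T
    grads["W1"] = np.einsum("blc,bld->cd", Xpad, dZ1)
    grads["b1"] = dZ1.sum(axis=(0, 1))
    return grads


class Adam:
    """Plain Adam over a parameter dict."""

    def __init__(self, params: dict, lr: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = zero_like_params(params)
        self.v = zero_like_params(params)
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1.0 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1.0 - self.beta2) * g * g
            mhat = self.m[k] / b1t
            vhat = self.v[k] / b2t
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
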