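"""Numerical core of the BiLSTM sequence classifier.

A standard LSTM cell (input/forget/output gates via the logistic sigmoid,
candidate via tanh):

    i_t = sigma(x_t Wx_i + h_{t-1} Wh_i + b_i)
    f_t = sigma(x_t Wx_f + h_{t-1} Wh_f + b_f)
    g_t = tanh (x_t Wx_g + h_{t-1} Wh_g + b_g)
    o_t = sigma(x_t Wx_o + h_{t-1} Wh_o + b_o)
    c_t = f_t * c_{t-1} + i_t * g_t
    h_t = o_t * tanh(c_t)

is run over the sequence in both directions; the final hidden states of the
two directions are concatenated and fed through one fully-connected layer
and a softmax. Training minimizes cross-entropy via exact backpropagation
through time and Adam. Everything is plain numpy with explicit analytic
gradients (verified against numerical differentiation in the test suite).

Parameter layout: per direction d in {"f", "b"} (forward/backward),
``Wx_d`` [D, 4H], ``Wh_d`` [H, 4H], ``b_d`` [4H] with gates stacked in the
order (i, f, g, o); readout ``W_out`` [2H, R], ``b_out`` [R].
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "sigmoid",
    "softmax",
    "init_params",
    "lstm_step",
    "lstm_run",
    "bilstm_forward",
    "bilstm_backward",
    "cross_entropy",
    "AdamOptimizer",
]


def sigmoid(z):
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def softmax(logits, axis=-1):
    z = logits - np.max(logits, axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def _glorot(rng, fan_in, fan_out, shape):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def init_params(n_channels: int, hidden_units: int, n_classes: int, rng) -> dict:
    """Seeded Glorot-uniform initialization; forget-gate bias set to 1."""
    D, H, R = n_channels, hidden_units, n_classes
    params = {}
    for d in ("f", "b"):
        params[f"Wx_{d}"] = _glorot(rng, D + H, 4 * H, (D, 4 * H))
        params[f"Wh_{d}"] = _glorot(rng, D + H, 4 * H, (H, 4 * H))
        b = np.zeros(4 * H)
        b[H:2 * H] = 1.0  # forget-gate bias: remember by default
        params[f"b_{d}"] = b
    params["W_out"] = _glorot(rng, 2 * H, R, (2 * H, R))
    params["b_out"] = np.zeros(R)
    return params


def lstm_step(x_t, h_prev, c_prev, params):
    """One LSTM cell update; returns (h_t, c_t).

    ``params`` is a dict with keys ``Wx`` [D, 4H], ``Wh`` [H, 4H], ``b``
    [4H]. Inputs may be single vectors or [batch, dim] matrices.
    """
    Wx, Wh, b = params["Wx"], params["Wh"], params["b"]
    x_t = np.atleast_2d(np.asarray(x_t, dtype=float))
    h_prev = np.atleast_2d(np.asarray(h_prev, dtype=float))
    c_prev = np.atleast_2d(np.asarray(c_prev, dtype=float))
    H = Wh.shape[0]
    if Wx.shape[1] != 4 * H or x_t.shape[1] != Wx.shape[0] or h_prev.shape[1] != H or c_prev.shape[1] != H:
        raise ValueError("inconsistent shapes in lstm_step")
    z = x_t @ Wx + h_prev @ Wh + b
    i = sigmoid(z[:, :H])
    f = sigmoid(z[:, H:2 * H])
    g = np.tanh(z[:, 2 * H:3 * H])
    o = sigmoid(z[:, 3 * H:])
    c = f * c_prev + i * g
    h = o * np.tanh(c)
    return np.squeeze(h), np.squeeze(c)


def _run_direction(X, Wx, Wh, b, keep_cache):
    """Batched LSTM over [B, T, D]; returns final h and (optionally) caches."""
    B, T, D = X.shape
    H = Wh.shape[0]
    Zx = X.reshape(B * T, D) @ Wx
    Zx = Zx.reshape(B, T, 4 * H) + b
    h = np.zeros((B, H))
    c = np.zeros((B, H))
    cache = None
    if keep_cache:
        cache = {k: np.empty((T, B, H), dtype=X.dtype)
                 for k in ("i", "f", "g", "o", "c", "h_prev", "c_prev")}
    for t in range(T):
        z = Zx[:, t] + h @ Wh
        i = sigmoid(z[:, :H])
        f = sigmoid(z[:, H:2 * H])
        g = np.tanh(z[:, 2 * H:3 * H])
        o = sigmoid(z[:, 3 * H:])
        if keep_cache:
            cache["h_prev"][t] = h
            cache["c_prev"][t] = c
        c = f * c + i * g
        h = o * np.tanh(c)
        if keep_cache:
            cache["i"][t], cache["f"][t], cache["g"][t], cache["o"][t], cache["c"][t] = i, f, g, o, c
    return h, cache


def lstm_run(X, Wx, Wh, b):
    """Final hidden state of one direction over batch X [B, T, D]."""
    h, _ = _run_direction(np.asarray(X, dtype=float), Wx, Wh, b, keep_cache=False)
    return h


def bilstm_forward(X, params, return_cache=False):
    """Class probabilities [B, R] for batch X [B, T, D].

    Final forward-direction state and final backward-direction state are
    concatenated before the fully-connected layer.
    """
    X = np.asarray(X)
    if X.dtype not in (np.float32, np.float64):
        X = X.astype(float)
    if X.ndim == 2:
        X = X[None]
    if X.shape[1] == 0:
        raise ValueError("empty sequence")
    hf, cf = _run_direction(X, params["Wx_f"], params["Wh_f"], params["b_f"], return_cache)
    Xr = X[:, ::-1]
    hb, cb = _run_direction(Xr, params["Wx_b"], params["Wh_b"], params["b_b"], return_cache)
    feat = np.concatenate([hf, hb], axis=1)
    logits = feat @ params["W_out"] + params["b_out"]
    probs = softmax(logits)
    if return_cache:
        return probs, {"X": X, "Xr": Xr, "feat": feat, "cache_f": cf, "cache_b": cb}
    return probs


def cross_entropy(probs, y):
    """Mean cross-entropy of true labels y under predicted probabilities."""
    p = np.clip(probs[np.arange(len(y)), y], 1e-30, None)
    return float(-np.mean(np.log(p)))


def _backward_direction(X, dh_final, Wh, cache):
    """BPTT through one direction given gradient w.r.t. the final state."""
    T, B, H = cache["i"].shape
    dZ = np.empty((T, B, 4 * H), dtype=cache["i"].dtype)
    dh = dh_final
    dc = np.zeros_like(dh)
    for t in range(T - 1, -1, -1):
        i, f, g, o = cache["i"][t], cache["f"][t], cache["g"][t], cache["o"][t]
        c, c_prev = cache["c"][t], cache["c_prev"][t]
        tc = np.tanh(c)
        do = dh * tc
        dc = dc + dh * o * (1.0 - tc * tc)
        di = dc * g
        df = dc * c_prev
        dg = dc * i
        dz = np.concatenate(
            [di * i * (1 - i), df * f * (1 - f), dg * (1 - g * g), do * o * (1 - o)], axis=1
        )
        dZ[t] = dz
        dh = dz @ Wh.T
        dc = dc * f
    H_prev = cache["h_prev"]  # [T, B, H]
    dWx = X.reshape(-1, X.shape[2]).T @ dZ.transpose(1, 0, 2).reshape(-1, 4 * H)
    dWh = np.einsum("tbh,tbk->hk", H_prev, dZ)
    db = dZ.sum(axis=(0, 1))
    return dWx, dWh, db


def bilstm_backward(y, probs, params, fwd_cache):
    """Gradients of mean cross-entropy w.r.t. every parameter."""
    X, Xr, feat = fwd_cache["X"], fwd_cache["Xr"], fwd_cache["feat"]
    B = X.shape[0]
    H = params["Wh_f"].shape[0]
    dlogits = probs.copy()
    dlogits[np.arange(B), y] -= 1.0
    dlogits /= B
    grads = {
        "W_out": feat.T @ dlogits,
        "b_out": dlogits.sum(axis=0),
    }
    dfeat = dlogits @ params["W_out"].T
    dWx, dWh, db = _backward_direction(X, dfeat[:, :H], params["Wh_f"], fwd_cache["cache_f"])
    grads["Wx_f"], grads["Wh_f"], grads["b_f"] = dWx, dWh, db
    dWx, dWh, db = _backward_direction(Xr, dfeat[:, H:], params["Wh_b"], fwd_cache["cache_b"])
    grads["Wx_b"], grads["Wh_b"], grads["b_b"] = dWx, dWh, db
    return grads


class AdamOptimizer:
    """Adam with bias correction; operates in place on a parameter dict."""

    def __init__(self, params, learning_rate=0.01, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr = learning_rate
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params, grads):
        self.t += 1
        for k in params:
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
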