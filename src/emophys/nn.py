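"""NumPy implementation of the attention 1D-CNN-GRU network.

Layer sequence (the feature vector is treated as a length-F, one-channel
sequence):

    Conv1D(ReLU) -> Conv1D(ReLU) -> MaxPool1D -> GRU -> additive attention
    -> Dense(ReLU) -> Dense -> softmax

Forward, backward (full BPTT through the GRU) and the Adam update are all
explicit, which keeps training bit-deterministic for a fixed seed on a
fixed BLAS configuration.

Shapes: batch B, sequence length F, conv channels C, pooled length T,
GRU units H, attention dim A, dense units D, classes K.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "softmax",
    "categorical_cross_entropy",
    "init_params",
    "forward",
    "backward",
    "AdamState",
    "adam_step",
    "attention_pool",
]

LOG_EPS = 1e-7


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    """Numerically stable softmax; rows sum to 1 for any finite logits."""
    z = logits - np.max(logits, axis=axis, keepdims=True)
    e = np.exp(z)
    return e / np.sum(e, axis=axis, keepdims=True)


def categorical_cross_entropy(
    y_true: np.ndarray, y_pred: np.ndarray, eps: float = LOG_EPS
) -> float:
    """Mean over samples of -sum_i y_i log yhat_i (probabilities clipped
    to [eps, 1] before the log)."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape:
        raise ValueError(f"shape mismatch {y_true.shape} vs {y_pred.shape}")
    row_sums = y_pred.sum(axis=-1)
    if not np.allclose(row_sums, 1.0, atol=1e-4):
        raise ValueError("predicted rows must sum to 1")
    logp = np.log(np.clip(y_pred, eps, 1.0))
    return float(-np.mean(np.sum(y_true * logp, axis=-1)))


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _glorot(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    fan_in, fan_out = shape[0] if len(shape) == 2 else int(np.prod(shape[:-1])), shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def init_params(config, n_features: int, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Glorot-uniform initial weights for every layer, in a flat dict."""
    k = config.kernel_size
    c1, c2 = config.conv1_filters, config.conv2_filters
    H, A, D, K = config.gru_units, config.attention_dim, config.dense_units, config.n_classes
    if n_features < k:
        raise ValueError(f"n_features={n_features} smaller than kernel size {k}")
    p = {
        "Wc1": _glorot(rng, (k, 1, c1)), "bc1": np.zeros(c1),
        "Wc2": _glorot(rng, (k, c1, c2)), "bc2": np.zeros(c2),
        "Wz": _glorot(rng, (c2, H)), "Uz": _glorot(rng, (H, H)), "bz": np.zeros(H),
        "Wr": _glorot(rng, (c2, H)), "Ur": _glorot(rng, (H, H)), "br": np.zeros(H),
        "Wn": _glorot(rng, (c2, H)), "Un": _glorot(rng, (H, H)), "bn": np.zeros(H),
        "Wa": _glorot(rng, (H, A)), "ba": np.zeros(A), "va": _glorot(rng, (A, 1))[:, 0],
        "Wd": _glorot(rng, (H, D)), "bd": np.zeros(D),
        "Wo": _glorot(rng, (D, K)), "bo": np.zeros(K),
    }
    return p


def _conv1d_same(x: np.ndarray, W: np.ndarray, b: np.ndarray) -> np.ndarray:
    """'same'-padded 1D convolution: x (B,F,Cin), W (k,Cin,Cout)."""
    k = W.shape[0]
    pad_l, pad_r = (k - 1) // 2, k // 2
    xp = np.pad(x, ((0, 0), (pad_l, pad_r), (0, 0)))
    F = x.shape[1]
    out = np.zeros((x.shape[0], F, W.shape[2]))
    for i in range(k):
        out += xp[:, i:i + F, :] @ W[i]
    return out + b


def _conv1d_same_backward(dY, x, W):
    """Gradients of _conv1d_same w.r.t. x, W, b."""
    k = W.shape[0]
    pad_l, pad_r = (k - 1) // 2, k // 2
    xp = np.pad(x, ((0, 0), (pad_l, pad_r), (0, 0)))
    F = x.shape[1]
    dW = np.zeros_like(W)
    dxp = np.zeros_like(xp)
    for i in range(k):
        dW[i] = np.einsum("bfc,bfo->co", xp[:, i:i + F, :], dY)
        dxp[:, i:i + F, :] += dY @ W[i].T
    db = dY.sum(axis=(0, 1))
    dx = dxp[:, pad_l:pad_l + F, :]
    return dx, dW, db


def attention_pool(Hseq: np.ndarray, Wa, ba, va):
    """Additive attention over GRU timesteps.

    Scores e_t = va . tanh(h_t Wa + ba) are softmax-normalized into weights
    alpha (nonnegative, summing to 1 over timesteps); returns the context
    vector sum_t alpha_t h_t along with (alpha, u) for backprop.
    """
    u = np.tanh(Hseq @ Wa + ba)  # (B,T,A)
    e = u @ va  # (B,T)
    alpha = softmax(e, axis=1)
    context = np.einsum("bt,bth->bh", alpha, Hseq)
    return context, alpha, u


def forward(params: dict, X: np.ndarray, config) -> tuple[np.ndarray, dict]:
    """Forward pass. X is (B, n_features); returns (probs, cache)."""
    p = params
    x0 = X[:, :, None]  # (B,F,1)
    a1 = _conv1d_same(x0, p["Wc1"], p["bc1"])
    h1 = np.maximum(a1, 0.0)
    a2 = _conv1d_same(h1, p["Wc2"], p["bc2"])
    h2 = np.maximum(a2, 0.0)
    # max pooling (stride = size); trailing remainder dropped
    ps = config.pool_size
    B, F, C = h2.shape
    T = F // ps
    if T < 1:
        raise ValueError(f"sequence length {F} shorter than pool size {ps}")
    blocks = h2[:, : T * ps, :].reshape(B, T, ps, C)
    pool_arg = blocks.argmax(axis=2)
    pooled = blocks.max(axis=2)  # (B,T,C)
    # GRU over T timesteps
    Hn = config.gru_units
    h = np.zeros((B, Hn))
    gates = []
    Hseq = np.empty((B, T, Hn))
    for t in range(T):
        xt = pooled[:, t, :]
        z = _sigmoid(xt @ p["Wz"] + h @ p["Uz"] + p["bz"])
        r = _sigmoid(xt @ p["Wr"] + h @ p["Ur"] + p["br"])
        n = np.tanh(xt @ p["Wn"] + (r * h) @ p["Un"] + p["bn"])
        h_new = (1.0 - z) * n + z * h
        gates.append((z, r, n, h))
        h = h_new
        Hseq[:, t, :] = h
    context, alpha, u = attention_pool(Hseq, p["Wa"], p["ba"], p["va"])
    ad = context @ p["Wd"] + p["bd"]
    d = np.maximum(ad, 0.0)
    logits = d @ p["Wo"] + p["bo"]
    probs = softmax(logits)
    cache = {
        "X": X, "x0": x0, "a1": a1, "h1": h1, "a2": a2, "h2": h2,
        "pool_arg": pool_arg, "pooled": pooled, "gates": gates, "Hseq": Hseq,
        "alpha": alpha, "u": u, "context": context, "ad": ad, "d": d,
        "probs": probs, "T": T,
    }
    return probs, cache


def backward(params: dict, cache: dict, Y: np.ndarray, config) -> dict[str, np.ndarray]:
    """Gradients of the mean cross-entropy loss w.r.t. every parameter."""
    p = params
    B = Y.shape[0]
    grads = {k: np.zeros_like(v) for k, v in p.items()}
    dlogits = (cache["probs"] - Y) / B
    grads["Wo"] = cache["d"].T @ dlogits
    grads["bo"] = dlogits.sum(axis=0)
    dd = dlogits @ p["Wo"].T
    dad = dd * (cache["ad"] > 0)
    grads["Wd"] = cache["context"].T @ dad
    grads["bd"] = dad.sum(axis=0)
    dc = dad @ p["Wd"].T  # (B,H)

    Hseq, alpha, u = cache["Hseq"], cache["alpha"], cache["u"]
    dHseq = alpha[:, :, None] * dc[:, None, :]
    dalpha = np.einsum("bh,bth->bt", dc, Hseq)
    de = alpha * (dalpha - np.sum(alpha * dalpha, axis=1, keepdims=True))
    du = de[:, :, None] * p["va"]
    grads["va"] = np.einsum("bta,bt->a", u, de)
    ds = du * (1.0 - u**2)
    grads["Wa"] = np.einsum("bth,bta->ha", Hseq, ds)
    grads["ba"] = ds.sum(axis=(0, 1))
    dHseq = dHseq + ds @ p["Wa"].T

    # BPTT through the GRU
    T = cache["T"]
    pooled = cache["pooled"]
    dpooled = np.zeros_like(pooled)
    dh_next = np.zeros((B, config.gru_units))
    for t in range(T - 1, -1, -1):
        z, r, n, h_prev = cache["gates"][t]
        dh = dHseq[:, t, :] + dh_next
        dn = dh * (1.0 - z)
        dan = dn * (1.0 - n**2)
        dz = dh * (h_prev - n)
        daz = dz * z * (1.0 - z)
        dr = (dan @ p["Un"].T) * h_prev
        dar = dr * r * (1.0 - r)
        xt = pooled[:, t, :]
        grads["Wz"] += xt.T @ daz
        grads["Wr"] += xt.T @ dar
        grads["Wn"] += xt.T @ dan
        grads["Uz"] += h_prev.T @ daz
        grads["Ur"] += h_prev.T @ dar
        grads["Un"] += (r * h_prev).T @ dan
        grads["bz"] += daz.sum(axis=0)
        grads["br"] += dar.sum(axis=0)
        grads["bn"] += dan.sum(axis=0)
        dpooled[:, t, :] = daz @ p["Wz"].T + dar @ p["Wr"].T + dan @ p["Wn"].T
        dh_next = dh * z + (dan @ p["Un"].T) * r + daz @ p["Uz"].T + dar @ p["Ur"].T

    # unpool (route gradient to the argmax positions)
    ps = config.pool_size
    h2 = cache["h2"]
    B_, F, C = h2.shape
    dh2 = np.zeros_like(h2)
    bidx = np.arange(B_)[:, None, None]
    tidx = np.arange(T)[None, :, None]
    cidx = np.arange(C)[None, None, :]
    flat_pos = tidx * ps + cache["pool_arg"]
    dh2[bidx, flat_pos, cidx] = dpooled

    da2 = dh2 * (cache["a2"] > 0)
    dh1, grads["Wc2"], grads["bc2"] = _conv1d_same_backward(da2, cache["h1"], p["Wc2"])
    da1 = dh1 * (cache["a1"] > 0)
    _, grads["Wc1"], grads["bc1"] = _conv1d_same_backward(da1, cache["x0"], p["Wc1"])
    return grads


class AdamState:
    """First/second-moment accumulators for the Adam optimizer."""

    def __init__(self, params: dict, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}


def adam_step(params: dict, grads: dict, state: AdamState) -> None:
    """In-place Adam update."""
    state.t += 1
    b1, b2 = state.beta1, state.beta2
    bc1 = 1.0 - b1**state.t
    bc2 = 1.0 - b2**state.t
    for k in params:
        state.m[k] = b1 * state.m[k] + (1 - b1) * grads[k]
        state.v[k] = b2 * state.v[k] + (1 - b2) * grads[k] ** 2
        mhat = state.m[k] / bc1
        vhat = state.v[k] / bc2
        params[k] -= state.lr * mhat / (np.sqrt(vhat) + state.eps)
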