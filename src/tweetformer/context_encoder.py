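"""Contextual fusion: two stacked bidirectional LSTM layers.

The 600-d position+word embeddings pass through two BiLSTM layers (150
units per direction, so 300-d per layer output). The encoder output is a
weighted sum of three 300-d streams — a learned linear projection of the
raw embeddings, the first layer's outputs, and the second layer's outputs —
with softmax-normalized learned fusion weights, so the mix is always a
convex combination. Dropout is applied to the two LSTM streams during
training only.

Masking follows the usual recurrent convention for right-padded batches:
a masked step carries the hidden/cell state through unchanged and emits a
zero output row, which makes trimming trailing padding exact.

Everything is plain NumPy with hand-derived backward passes; gradients are
verified against central finite differences in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = ["ContextEncoderParams", "init_context_params", "bilstm_layer", "context_encode"]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _glorot(rng: np.random.Generator, shape: tuple[int, ...], dtype) -> np.ndarray:
    fan_in, fan_out = shape[0], shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


def init_lstm_direction(rng: np.random.Generator, d_in: int, hidden: int, dtype=np.float32) -> dict[str, np.ndarray]:
    """One direction's parameters; gate order is (input, forget, cell, output).

    The forget-gate bias starts at 1 (the usual trick that keeps early cell
    state from washing out).
    """
    b = np.zeros(4 * hidden, dtype=dtype)
    b[hidden : 2 * hidden] = 1.0
    return {
        "W": _glorot(rng, (d_in, 4 * hidden), dtype),
        "U": _glorot(rng, (hidden, 4 * hidden), dtype),
        "b": b,
    }


def _lstm_direction_forward(X: np.ndarray, mask: np.ndarray, p: dict, reverse: bool):
    """X: (B, T, d_in); mask: (B, T) float {0,1}. Returns (B, T, H) and cache."""
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite inputs to LSTM layer")
    B, T, _ = X.shape
    H = p["U"].shape[0]
    Z0 = X @ p["W"] + p["b"]
    h = np.zeros((B, H), dtype=X.dtype)
    c = np.zeros((B, H), dtype=X.dtype)
    out = np.zeros((B, T, H), dtype=X.dtype)
    steps = range(T - 1, -1, -1) if reverse else range(T)
    cache_steps = []
    for t in steps:
        z = Z0[:, t] + h @ p["U"]
        i = _sigmoid(z[:, :H])
        f = _sigmoid(z[:, H : 2 * H])
        g = np.tanh(z[:, 2 * H : 3 * H])
        o = _sigmoid(z[:, 3 * H :])
        c_new = f * c + i * g
        tc = np.tanh(c_new)
        h_new = o * tc
        m = mask[:, t : t + 1]
        out[:, t] = m * h_new
        cache_steps.append((t, i, f, g, o, c, h, tc))
        h = m * h_new + (1.0 - m) * h
        c = m * c_new + (1.0 - m) * c
    return out, {"X": X, "mask": mask, "steps": cache_steps, "H": H, "p": p}


def _lstm_direction_backward(cache: dict, dOut: np.ndarray):
    X, mask, H, p = cache["X"], cache["mask"], cache["H"], cache["p"]
    B, T, _ = X.shape
    dW = np.zeros_like(p["W"])
    dU = np.zeros_like(p["U"])
    db = np.zeros_like(p["b"])
    dX = np.zeros_like(X)
    dh = np.zeros((B, H), dtype=X.dtype)
    dc = np.zeros((B, H), dtype=X.dtype)
    for t, i, f, g, o, c_prev, h_prev, tc in reversed(cache["steps"]):
        m = mask[:, t : t + 1]
        dh_new = m * (dOut[:, t] + dh)
        dh_carry = (1.0 - m) * dh
        dc_new = m * dc
        dc_carry = (1.0 - m) * dc
        do = dh_new * tc
        dc_new = dc_new + dh_new * o * (1.0 - tc * tc)
        df = dc_new * c_prev
        di = dc_new * g
        dg = dc_new * i
        dc = dc_new * f + dc_carry
        dz = np.concatenate(
            [di * i * (1.0 - i), df * f * (1.0 - f), dg * (1.0 - g * g), do * o * (1.0 - o)],
            axis=1,
        )
        dW += X[:, t].T @ dz
        dU += h_prev.T @ dz
        db += dz.sum(axis=0)
        dX[:, t] += dz @ p["W"].T
        dh = dz @ p["U"].T + dh_carry
    return {"W": dW, "U": dU, "b": db}, dX


def bilstm_layer(inputs: np.ndarray, params: dict, mask: Optional[np.ndarray] = None):
    """One bidirectional layer.

    ``inputs``: (B, T, d_in) or (T, d_in); ``params`` holds ``fw`` and
    ``bw`` direction dicts. Returns per-position concatenation of the
    forward and backward outputs — width 2·H — plus a cache for backward.
    """
    squeeze = inputs.ndim == 2
    if squeeze:
        inputs = inputs[None]
        mask = None if mask is None else np.asarray(mask)[None]
    B, T, _ = inputs.shape
    m = np.ones((B, T), dtype=inputs.dtype) if mask is None else np.asarray(mask).astype(inputs.dtype)
    out_f, cache_f = _lstm_direction_forward(inputs, m, params["fw"], reverse=False)
    out_b, cache_b = _lstm_direction_forward(inputs, m, params["bw"], reverse=True)
    out = np.concatenate([out_f, out_b], axis=-1)
    if squeeze:
        out = out[0]
    return out, {"f": cache_f, "b": cache_b, "H": params["fw"]["U"].shape[0], "squeeze": squeeze}


def bilstm_layer_backward(cache: dict, dOut: np.ndarray):
    if cache["squeeze"]:
        dOut = dOut[None]
    H = cache["H"]
    d_f, dX_f = _lstm_direction_backward(cache["f"], np.ascontiguousarray(dOut[..., :H]))
    d_b, dX_b = _lstm_direction_backward(cache["b"], np.ascontiguousarray(dOut[..., H:]))
    dX = dX_f + dX_b
    if cache["squeeze"]:
        dX = dX[0]
    return {"fw": d_f, "bw": d_b}, dX


@dataclass
class ContextEncoderParams:
    """All Phase-I context parameters.

    ``proj_W``/``proj_b`` project the 600-d embeddings to the 300-d stream
    that joins the fusion sum; ``layer1``/``layer2`` are the BiLSTM layers;
    ``fusion_logits`` are the three learned mixing scores.
    """

    proj_W: np.ndarray  # (2·dim, 2·H)
    proj_b: np.ndarray  # (2·H,)
    layer1: dict
    layer2: dict
    fusion_logits: np.ndarray  # (3,)
    dropout_rate: float = 0.3


def init_context_params(
    rng: np.random.Generator,
    embed_dim: int = 300,
    hidden: int = 150,
    dropout_rate: float = 0.3,
    dtype=np.float32,
) -> ContextEncoderParams:
    d_in = 2 * embed_dim
    d_out = 2 * hidden
    return ContextEncoderParams(
        proj_W=_glorot(rng, (d_in, d_out), dtype),
        proj_b=np.zeros(d_out, dtype=dtype),
        layer1={
            "fw": init_lstm_direction(rng, d_in, hidden, dtype),
            "bw": init_lstm_direction(rng, d_in, hidden, dtype),
        },
        layer2={
            "fw": init_lstm_direction(rng, d_out, hidden, dtype),
            "bw": init_lstm_direction(rng, d_out, hidden, dtype),
        },
        fusion_logits=np.zeros(3, dtype=dtype),
        dropout_rate=dropout_rate,
    )


def fusion_weights(params: ContextEncoderParams) -> np.ndarray:
    z = params.fusion_logits - params.fusion_logits.max()
    e = np.exp(z)
    return e / e.sum()


def context_encode(
    embedded: np.ndarray,
    params: ContextEncoderParams,
    mask: Optional[np.ndarray] = None,
    train: bool = False,
    dropout_rng: Optional[np.random.Generator] = None,
):
    """Fuse projection and BiLSTM streams into (…, T, 2·H) context vectors.

    output = w0·proj(embedded) + w1·BiLSTM1(embedded) + w2·BiLSTM2(BiLSTM1),
    with (w0, w1, w2) = softmax(fusion_logits). In training mode inverted
    dropout is applied to the two LSTM streams.
    """
    squeeze = embedded.ndim == 2
    E = embedded[None] if squeeze else embedded
    m = None if mask is None else (np.asarray(mask)[None] if squeeze else np.asarray(mask))
    h0 = E @ params.proj_W + params.proj_b
    h1, cache1 = bilstm_layer(E, params.layer1, m)
    h2, cache2 = bilstm_layer(h1, params.layer2, m)
    if train and params.dropout_rate > 0.0:
        if dropout_rng is None:
            raise ValueError("training mode needs a dropout RNG")
        keep = 1.0 - params.dropout_rate
        d1 = (dropout_rng.random(h1.shape) < keep).astype(E.dtype) / keep
        d2 = (dropout_rng.random(h2.shape) < keep).astype(E.dtype) / keep
    else:
        d1 = d2 = None
    h1d = h1 if d1 is None else h1 * d1
    h2d = h2 if d2 is None else h2 * d2
    w = fusion_weights(params).astype(E.dtype)
    out = w[0] * h0 + w[1] * h1d + w[2] * h2d
    if squeeze:
        out = out[0]
    cache = {
        "E": E, "h0": h0, "h1": h1, "h2": h2, "h1d": h1d, "h2d": h2d,
        "d1": d1, "d2": d2, "w": w, "c1": cache1, "c2": cache2,
        "params": params, "squeeze": squeeze,
    }
    return out, cache


def context_encode_backward(cache: dict, dOut: np.ndarray):
    """Returns (grads dict mirroring ContextEncoderParams, d_embedded)."""
    if cache["squeeze"]:
        dOut = dOut[None]
    p: ContextEncoderParams = cache["params"]
    w = cache["w"]
    dh0 = w[0] * dOut
    dh1d = w[1] * dOut
    dh2d = w[2] * dOut
    # fusion weights: dL/dw_j = <dOut, h_j>, then softmax backward
    dw = np.array(
        [float((dOut * cache["h0"]).sum()), float((dOut * cache["h1d"]).sum()), float((dOut * cache["h2d"]).sum())]
    )
    dlogits = (w * (dw - float((dw * w).sum()))).astype(p.fusion_logits.dtype)
    dh1 = dh1d if cache["d1"] is None else dh1d * cache["d1"]
    dh2 = dh2d if cache["d2"] is None else dh2d * cache["d2"]
    g2, dh1_from_l2 = bilstm_layer_backward(cache["c2"], dh2)
    dh1 = dh1 + dh1_from_l2
    g1, dE_l1 = bilstm_layer_backward(cache["c1"], dh1)
    E = cache["E"]
    B, T, d_in = E.shape
    dproj_W = E.reshape(-1, d_in).T @ dh0.reshape(-1, dh0.shape[-1])
    dproj_b = dh0.sum(axis=(0, 1))
    dE = dE_l1 + dh0 @ p.proj_W.T
    if cache["squeeze"]:
        dE = dE[0]
    grads = {
        "proj_W": dproj_W, "proj_b": dproj_b,
        "layer1": g1, "layer2": g2,
        "fusion_logits": dlogits,
    }
    return grads, dE
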