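"""Linear-complexity additive attention with global query/key summaries.

Instead of pairwise query–key dot products (O(N²)), each head:

1. scores every query vector against a learned vector ``w_q``
   (``α = softmax(w_qᵀ q_i / √d_h)``) and pools ``q = Σ α_i q_i`` — the
   *global query*;
2. forms context-aware keys ``p_i = q ⊙ k_i``, scores them against ``w_k``
   the same way, and pools the *global key* ``k = Σ β_i p_i``;
3. modulates values ``u_i = k ⊙ v_i``, maps them through a linear layer to
   ``r_i``, and emits ``r_i + q_i`` (residual to the query).

Every step touches each position once, so cost and memory grow O(N·d); no
N×N matrix ever exists. Heads are concatenated and projected back to the
model width. The scoring vectors ``w_q``/``w_k`` are updated through an
exponentially weighted moving average of their gradients
(``V_t = ρ V_{t-1} + (1-ρ) g_t``, ρ = 0.8) rather than the raw gradient.

The batched multi-head core (`stacked_forward`/`stacked_backward`) is the
single implementation; the per-instance functions are thin views of it used
by the public API and checked in tests against a naive per-token oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "AttentionHeadParams",
    "EncoderParams",
    "init_encoder_params",
    "additive_pool",
    "head_forward",
    "encoder_forward",
    "ewma_update",
    "stacked_forward",
    "stacked_backward",
]


@dataclass
class AttentionHeadParams:
    """One head: Q/K/V projections, scoring vectors, output transform.

    ``Vdw_q``/``Vdw_k`` are the EWMA gradient buffers for the scoring
    vectors; ``rho`` is the averaging coefficient.
    """

    Wq_proj: np.ndarray  # (d_model, d_h)
    Wk_proj: np.ndarray
    Wv_proj: np.ndarray
    w_q: np.ndarray  # (d_h,)
    w_k: np.ndarray  # (d_h,)
    Wr: np.ndarray  # (d_h, d_h)
    br: np.ndarray  # (d_h,)
    Vdw_q: np.ndarray = field(default=None)  # type: ignore[assignment]
    Vdw_k: np.ndarray = field(default=None)  # type: ignore[assignment]
    rho: float = 0.8

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho < 1.0:
            raise ValueError("rho must be in [0, 1)")
        if self.Vdw_q is None:
            self.Vdw_q = np.zeros_like(self.w_q)
        if self.Vdw_k is None:
            self.Vdw_k = np.zeros_like(self.w_k)

    @property
    def d_h(self) -> int:
        return self.Wq_proj.shape[1]


@dataclass
class EncoderParams:
    """A full encoder block: 16 heads plus the concat→model-width projection."""

    heads: list[AttentionHeadParams]
    output_projection: np.ndarray  # (n_heads·d_h, d_model)
    output_bias: np.ndarray  # (d_model,)

    @property
    def n_heads(self) -> int:
        return len(self.heads)

    @property
    def d_h(self) -> int:
        return self.heads[0].d_h

    @property
    def d_model(self) -> int:
        return self.heads[0].Wq_proj.shape[0]


def _glorot(rng: np.random.Generator, shape: tuple[int, ...], dtype) -> np.ndarray:
    limit = np.sqrt(6.0 / (shape[0] + shape[-1]))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


def init_encoder_params(
    rng: np.random.Generator,
    d_model: int = 300,
    n_heads: int = 16,
    d_h: int = 32,
    rho: float = 0.8,
    dtype=np.float32,
) -> EncoderParams:
    heads = []
    for _ in range(n_heads):
        heads.append(
            AttentionHeadParams(
                Wq_proj=_glorot(rng, (d_model, d_h), dtype),
                Wk_proj=_glorot(rng, (d_model, d_h), dtype),
                Wv_proj=_glorot(rng, (d_model, d_h), dtype),
                w_q=(rng.standard_normal(d_h) / np.sqrt(d_h)).astype(dtype),
                w_k=(rng.standard_normal(d_h) / np.sqrt(d_h)).astype(dtype),
                Wr=_glorot(rng, (d_h, d_h), dtype),
                br=np.zeros(d_h, dtype=dtype),
                rho=rho,
            )
        )
    return EncoderParams(
        heads=heads,
        output_projection=_glorot(rng, (n_heads * d_h, d_model), dtype),
        output_bias=np.zeros(d_model, dtype=dtype),
    )


def stack_heads(params: EncoderParams) -> dict[str, np.ndarray]:
    """Stack per-head arrays along a leading head axis for the batched core."""
    return {
        "Wq": np.stack([h.Wq_proj for h in params.heads]),
        "Wk": np.stack([h.Wk_proj for h in params.heads]),
        "Wv": np.stack([h.Wv_proj for h in params.heads]),
        "wq": np.stack([h.w_q for h in params.heads]),
        "wk": np.stack([h.w_k for h in params.heads]),
        "Wr": np.stack([h.Wr for h in params.heads]),
        "br": np.stack([h.br for h in params.heads]),
        "Wout": params.output_projection,
        "bout": params.output_bias,
    }


def _masked_softmax(logits: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Softmax over the last axis restricted to mask==1 positions."""
    neg = np.finfo(logits.dtype).min
    z = np.where(mask > 0, logits, neg)
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z) * (mask > 0)
    return e / e.sum(axis=-1, keepdims=True)


def _softmax_backward(probs: np.ndarray, dprobs: np.ndarray) -> np.ndarray:
    inner = (dprobs * probs).sum(axis=-1, keepdims=True)
    return probs * (dprobs - inner)


def additive_pool(X: np.ndarray, w: np.ndarray, mask: Optional[np.ndarray] = None):
    """Additive-attention pooling of a sequence into one vector.

    ``logit_i = wᵀ x_i / √d_h`` on unmasked positions, softmax-normalized
    with max-subtraction; returns (weights (N,), pooled (d_h,)).
    """
    X = np.asarray(X)
    N, d_h = X.shape
    m = np.ones(N) if mask is None else np.asarray(mask).astype(float)
    if not m.any():
        raise ValueError("empty sequence: all positions masked")
    logits = (X @ np.asarray(w)) / np.sqrt(d_h)
    weights = _masked_softmax(logits.astype(np.float64), m)
    pooled = weights @ X
    return weights, pooled


def stacked_forward(
    E: np.ndarray,
    sp: dict[str, np.ndarray],
    mask: Optional[np.ndarray] = None,
    counter: Optional[dict] = None,
):
    """Batched multi-head forward. E: (B, T, d_model); mask: (B, T).

    Returns (Y (B, T, d_model), cache). When ``counter`` is given, the
    number of scalar multiplications of every tensor contraction and
    elementwise product is accumulated into ``counter["mults"]``.
    """
    B, T, D = E.shape
    Hh, _, K = sp["Wq"].shape
    m = np.ones((B, T), dtype=E.dtype) if mask is None else np.asarray(mask).astype(E.dtype)
    if not np.all(m.sum(axis=1) > 0):
        raise ValueError("empty sequence: all positions masked")
    scale = 1.0 / np.sqrt(K)

    Q = np.einsum("btd,hdk->bhtk", E, sp["Wq"], optimize=True)
    Km = np.einsum("btd,hdk->bhtk", E, sp["Wk"], optimize=True)
    V = np.einsum("btd,hdk->bhtk", E, sp["Wv"], optimize=True)
    s1 = np.einsum("bhtk,hk->bht", Q, sp["wq"], optimize=True) * scale
    alpha = _masked_softmax(s1, m[:, None, :])
    qg = np.einsum("bht,bhtk->bhk", alpha, Q, optimize=True)
    P = qg[:, :, None, :] * Km
    s2 = np.einsum("bhtk,hk->bht", P, sp["wk"], optimize=True) * scale
    beta = _masked_softmax(s2, m[:, None, :])
    kg = np.einsum("bht,bhtk->bhk", beta, P, optimize=True)
    Um = kg[:, :, None, :] * V
    R = np.einsum("bhtk,hkj->bhtj", Um, sp["Wr"], optimize=True) + sp["br"][None, :, None, :]
    Ohead = R + Q
    O = Ohead.transpose(0, 2, 1, 3).reshape(B, T, Hh * K)
    Y = O @ sp["Wout"] + sp["bout"]

    if counter is not None:
        mults = (
            3 * B * T * D * Hh * K  # Q/K/V projections
            + 2 * B * Hh * T * K  # the two scoring contractions
            + 2 * B * Hh * T * K  # the two pooling sums
            + 2 * B * Hh * T * K  # the two elementwise modulations
            + B * Hh * T * K * K  # Wr transform
            + B * T * Hh * K * D  # output projection
        )
        counter["mults"] = counter.get("mults", 0) + int(mults)

    cache = {
        "E": E, "m": m, "sp": sp, "Q": Q, "K": Km, "V": V,
        "alpha": alpha, "qg": qg, "P": P, "beta": beta, "kg": kg,
        "U": Um, "O": O, "scale": scale,
    }
    return Y, cache


def stacked_backward(cache: dict, dY: np.ndarray):
    """Backward of `stacked_forward`; returns (grads dict, dE)."""
    sp = cache["sp"]
    E, m = cache["E"], cache["m"]
    Q, Km, V = cache["Q"], cache["K"], cache["V"]
    alpha, qg, P, beta, kg, Um = (
        cache["alpha"], cache["qg"], cache["P"], cache["beta"], cache["kg"], cache["U"],
    )
    scale = cache["scale"]
    B, T, D = E.shape
    Hh, _, K = sp["Wq"].shape

    dWout = cache["O"].reshape(-1, Hh * K).T @ dY.reshape(-1, D)
    dbout = dY.sum(axis=(0, 1))
    dO = (dY @ sp["Wout"].T).reshape(B, T, Hh, K).transpose(0, 2, 1, 3)
    dR = dO
    dQ = dO.copy()

    dWr = np.einsum("bhtk,bhtj->hkj", Um, dR, optimize=True)
    dbr = dR.sum(axis=(0, 2))
    dU = np.einsum("bhtj,hkj->bhtk", dR, sp["Wr"], optimize=True)

    dkg = (dU * V).sum(axis=2)
    dV = dU * kg[:, :, None, :]

    dbeta = np.einsum("bhk,bhtk->bht", dkg, P, optimize=True)
    dP = beta[..., None] * dkg[:, :, None, :]
    ds2 = _softmax_backward(beta, dbeta)
    dwk = np.einsum("bht,bhtk->hk", ds2, P, optimize=True) * scale
    dP += ds2[..., None] * sp["wk"][None, :, None, :] * scale

    dqg = (dP * Km).sum(axis=2)
    dK = dP * qg[:, :, None, :]

    dalpha = np.einsum("bhk,bhtk->bht", dqg, Q, optimize=True)
    dQ += alpha[..., None] * dqg[:, :, None, :]
    ds1 = _softmax_backward(alpha, dalpha)
    dwq = np.einsum("bht,bhtk->hk", ds1, Q, optimize=True) * scale
    dQ += ds1[..., None] * sp["wq"][None, :, None, :] * scale

    dWq = np.einsum("btd,bhtk->hdk", E, dQ, optimize=True)
    dWk = np.einsum("btd,bhtk->hdk", E, dK, optimize=True)
    dWv = np.einsum("btd,bhtk->hdk", E, dV, optimize=True)
    dE = (
        np.einsum("bhtk,hdk->btd", dQ, sp["Wq"], optimize=True)
        + np.einsum("bhtk,hdk->btd", dK, sp["Wk"], optimize=True)
        + np.einsum("bhtk,hdk->btd", dV, sp["Wv"], optimize=True)
    )
    grads = {
        "Wq": dWq, "Wk": dWk, "Wv": dWv, "wq": dwq, "wk": dwk,
        "Wr": dWr, "br": dbr, "Wout": dWout, "bout": dbout,
    }
    return grads, dE


def head_forward(E: np.ndarray, params: AttentionHeadParams, mask: Optional[np.ndarray] = None) -> np.ndarray:
    """One head on one sequence: E (N, d_model) -> (N, d_h)."""
    sp = {
        "Wq": params.Wq_proj[None], "Wk": params.Wk_proj[None], "Wv": params.Wv_proj[None],
        "wq": params.w_q[None], "wk": params.w_k[None],
        "Wr": params.Wr[None], "br": params.br[None],
        "Wout": np.eye(params.d_h, dtype=E.dtype), "bout": np.zeros(params.d_h, dtype=E.dtype),
    }
    m = None if mask is None else np.asarray(mask)[None]
    Y, _ = stacked_forward(np.asarray(E)[None], sp, m)
    return Y[0]


def encoder_forward(
    E: np.ndarray,
    params: EncoderParams,
    mask: Optional[np.ndarray] = None,
    counter: Optional[dict] = None,
) -> np.ndarray:
    """Full multi-head encoder block on one sequence: (N, d_model) -> (N, d_model)."""
    sp = stack_heads(params)
    m = None if mask is None else np.asarray(mask)[None]
    Y, _ = stacked_forward(np.asarray(E)[None], sp, m, counter=counter)
    return Y[0]


def ewma_update(buffer: np.ndarray, grad: np.ndarray, rho: float) -> np.ndarray:
    """Exponentially weighted moving average of gradients.

    ``V_t = ρ·V_{t-1} + (1-ρ)·g_t``; the optimizer consumes the returned
    buffer in place of the raw gradient for the scoring vectors.
    """
    buffer = np.asarray(buffer)
    grad = np.asarray(grad)
    if buffer.shape != grad.shape:
        raise ValueError(f"shape mismatch: {buffer.shape} vs {grad.shape}")
    if not 0.0 <= rho < 1.0:
        raise ValueError("rho must be in [0, 1)")
    return rho * buffer + (1.0 - rho) * grad
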