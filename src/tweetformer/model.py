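"""End-to-end position-context additive-attention classifier.

Pipeline: token ids -> hybrid position+word embeddings (600-d) -> two-layer
BiLSTM contextual fusion (300-d) -> additive-attention encoder block(s)
(300-d) -> masked mean pooling -> dense layer with sigmoid (binary /
multilabel) or softmax (multiclass) output.

Training follows the recipe the architecture was designed around: Adam at
3e-5 for 3 epochs, batch 64, linear warmup over the first 10% of steps then
linear decay to zero, classification threshold 0.5. The attention scoring
vectors w_q/w_k are updated from an exponentially weighted moving average
(rho = 0.8) of their gradients instead of the raw gradient.

Two ablation switches reproduce the reduced variants: ``use_position_vector``
(off: the word vector is duplicated instead of concatenated with a position
vector) and ``use_bilstm`` (off: the learned 600->300 input projection feeds
attention directly).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import attention as att
from . import context_encoder as ctx
from .embedder import EmbeddingTables, init_tables
from .tokenizer import TokenSequence, Vocabulary

__all__ = ["ModelConfig", "TrainingHistory", "TextClassifier", "lr_schedule"]


@dataclass
class ModelConfig:
    """Every architectural and training hyperparameter, plus all seeds."""

    n_classes: int = 2
    task_mode: str = "binary"  # binary | multiclass | multilabel
    max_len: int = 128
    embed_dim: int = 300
    lstm_hidden: int = 150  # per direction; d_model = 2·lstm_hidden
    n_heads: int = 16
    d_h: int = 32
    n_blocks: int = 1
    dropout: float = 0.3
    threshold: float = 0.5
    epochs: int = 3
    learning_rate: float = 3e-5
    batch_size: int = 64
    warmup_fraction: float = 0.10
    rho: float = 0.8
    use_ewma: bool = True
    use_position_vector: bool = True
    use_bilstm: bool = True
    train_positions: bool = False
    seed_init: int = 0
    seed_shuffle: int = 1
    seed_dropout: int = 2
    dtype: str = "float32"

    @property
    def d_model(self) -> int:
        return 2 * self.lstm_hidden

    @property
    def n_outputs(self) -> int:
        return 1 if self.task_mode == "binary" else self.n_classes

    def __post_init__(self) -> None:
        if self.task_mode not in ("binary", "multiclass", "multilabel"):
            raise ValueError(f"unknown task_mode {self.task_mode!r}")
        if self.task_mode == "binary" and self.n_classes != 2:
            raise ValueError("binary mode needs n_classes == 2")
        if not 0.0 <= self.warmup_fraction < 1.0:
            raise ValueError("warmup_fraction must be in [0, 1)")
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must be in (0, 1)")

    @property
    def np_dtype(self):
        return np.dtype(self.dtype)


@dataclass
class TrainingHistory:
    losses: list[float] = field(default_factory=list)
    lrs: list[float] = field(default_factory=list)
    val_metrics: list[dict] = field(default_factory=list)


def lr_schedule(step: int, total_steps: int, base_lr: float, warmup_fraction: float) -> float:
    """Linear warmup then linear decay to zero; ``step`` is 1-indexed."""
    warmup = int(np.ceil(warmup_fraction * total_steps))
    if warmup > 0 and step <= warmup:
        return base_lr * step / warmup
    return base_lr * (total_steps - step) / max(1, total_steps - warmup)


def _sigmoid(x):
    return ctx._sigmoid(x)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class TextClassifier:
    """The classifier: parameters, forward/backward, training, inference."""

    def __init__(self, config: ModelConfig, vocab: Vocabulary):
        self.config = config
        self.vocab = vocab
        cfg = config
        dt = cfg.np_dtype
        self.tables: EmbeddingTables = init_tables(
            vocab, max_len=cfg.max_len, dim=cfg.embed_dim, seed=cfg.seed_init, dtype=dt
        )
        self.tables.train_positions = cfg.train_positions
        rng = np.random.default_rng(cfg.seed_init + 1)
        self.ctx: ctx.ContextEncoderParams = ctx.init_context_params(
            rng, embed_dim=cfg.embed_dim, hidden=cfg.lstm_hidden, dropout_rate=cfg.dropout, dtype=dt
        )
        self.blocks: list[dict[str, np.ndarray]] = [
            att.stack_heads(att.init_encoder_params(rng, cfg.d_model, cfg.n_heads, cfg.d_h, cfg.rho, dt))
            for _ in range(cfg.n_blocks)
        ]
        self.ewma_buffers = [
            {"wq": np.zeros((cfg.n_heads, cfg.d_h), dtype=dt), "wk": np.zeros((cfg.n_heads, cfg.d_h), dtype=dt)}
            for _ in range(cfg.n_blocks)
        ]
        limit = np.sqrt(6.0 / (cfg.d_model + cfg.n_outputs))
        self.head_W = rng.uniform(-limit, limit, size=(cfg.d_model, cfg.n_outputs)).astype(dt)
        self.head_b = np.zeros(cfg.n_outputs, dtype=dt)

    # ---------------------------------------------------------------- params

    def encoder_params(self, block: int = 0) -> att.EncoderParams:
        """View of one attention block as structured per-head parameters."""
        sp = self.blocks[block]
        heads = [
            att.AttentionHeadParams(
                Wq_proj=sp["Wq"][h], Wk_proj=sp["Wk"][h], Wv_proj=sp["Wv"][h],
                w_q=sp["wq"][h], w_k=sp["wk"][h], Wr=sp["Wr"][h], br=sp["br"][h],
                Vdw_q=self.ewma_buffers[block]["wq"][h], Vdw_k=self.ewma_buffers[block]["wk"][h],
                rho=self.config.rho,
            )
            for h in range(self.config.n_heads)
        ]
        return att.EncoderParams(heads=heads, output_projection=sp["Wout"], output_bias=sp["bout"])

    def param_items(self, trainable_only: bool = True) -> list[tuple[str, np.ndarray]]:
        cfg = self.config
        items: list[tuple[str, np.ndarray]] = []
        items.append(("emb.word", self.tables.word_table))
        items.append(("emb.subunit", self.tables.subunit_table))
        if not trainable_only or cfg.train_positions:
            items.append(("emb.pos", self.tables.position_table))
        items.append(("ctx.proj_W", self.ctx.proj_W))
        items.append(("ctx.proj_b", self.ctx.proj_b))
        if not trainable_only or cfg.use_bilstm:
            for lname, layer in (("layer1", self.ctx.layer1), ("layer2", self.ctx.layer2)):
                for d in ("fw", "bw"):
                    for k in ("W", "U", "b"):
                        items.append((f"ctx.{lname}.{d}.{k}", layer[d][k]))
            items.append(("ctx.fusion_logits", self.ctx.fusion_logits))
        for i, sp in enumerate(self.blocks):
            for k in ("Wq", "Wk", "Wv", "wq", "wk", "Wr", "br", "Wout", "bout"):
                items.append((f"att{i}.{k}", sp[k]))
        items.append(("head.W", self.head_W))
        items.append(("head.b", self.head_b))
        return items

    def n_trainable_parameters(self) -> int:
        return sum(arr.size for _, arr in self.param_items(trainable_only=True))

    # --------------------------------------------------------------- batches

    def make_batch(self, seqs: Sequence[TokenSequence]):
        """Right-trim a batch to its longest sequence and stack arrays."""
        T = max(1, max(s.n_tokens for s in seqs))
        ids = np.stack([s.ids[:T] for s in seqs])
        mask = np.stack([s.mask[:T] for s in seqs])
        oovs = [
            (b, t, np.asarray(units, dtype=np.int64))
            for b, s in enumerate(seqs)
            for t, units in s.oov_map.items()
            if t < T
        ]
        labels = None
        if all(s.label is not None for s in seqs):
            labels = np.array([s.label for s in seqs], dtype=np.int64)
        return ids, mask, oovs, labels

    def _embed_batch(self, ids, mask, oovs):
        cfg = self.config
        dim = cfg.embed_dim
        X = self.tables.word_table[ids].copy()
        for b, t, units in oovs:
            X[b, t] = self.tables.subunit_table[units].sum(axis=0)
        X[~mask] = 0.0
        B, T = ids.shape
        E = np.empty((B, T, 2 * dim), dtype=X.dtype)
        E[:, :, :dim] = X
        if cfg.use_position_vector:
            pos = np.broadcast_to(self.tables.position_table[:T], (B, T, dim)).copy()
            pos[~mask] = 0.0
            E[:, :, dim:] = pos
        else:
            E[:, :, dim:] = X
        return E

    def _embed_backward(self, dE, ids, mask, oovs, grads):
        cfg = self.config
        dim = cfg.embed_dim
        dX = dE[:, :, :dim]
        if not cfg.use_position_vector:
            dX = dX + dE[:, :, dim:]
        gw = grads["emb.word"]
        gs = grads["emb.subunit"]
        oov_pos = np.zeros(ids.shape, dtype=bool)
        for b, t, _ in oovs:
            oov_pos[b, t] = True
        sel = mask & ~oov_pos
        np.add.at(gw, ids[sel], dX[sel])
        for b, t, units in oovs:
            np.add.at(gs, units, np.broadcast_to(dX[b, t], (len(units), dim)))
        gw[0] = 0.0  # padding row frozen
        if cfg.train_positions and cfg.use_position_vector:
            dpos = dE[:, :, dim:].copy()
            dpos[~mask] = 0.0
            grads["emb.pos"][: ids.shape[1]] += dpos.sum(axis=0)

    # --------------------------------------------------------------- forward

    def forward_arrays(self, ids, mask, train: bool = False, dropout_rng=None):
        cfg = self.config
        return self._forward(ids, mask, [], train, dropout_rng)

    def _forward(self, ids, mask, oovs, train, dropout_rng):
        cfg = self.config
        E = self._embed_batch(ids, mask, oovs)
        mf = mask.astype(E.dtype)
        if cfg.use_bilstm:
            C, ctx_cache = ctx.context_encode(E, self.ctx, mf, train=train, dropout_rng=dropout_rng)
        else:
            C = E @ self.ctx.proj_W + self.ctx.proj_b
            ctx_cache = None
        X = C
        att_caches = []
        for sp in self.blocks:
            X, cache = att.stacked_forward(X, sp, mf)
            att_caches.append(cache)
        msum = mf.sum(axis=1, keepdims=True)
        pooled = (X * mf[..., None]).sum(axis=1) / msum
        logits = pooled @ self.head_W + self.head_b
        if cfg.task_mode == "multiclass":
            probs = _softmax(logits)
        else:
            probs = _sigmoid(logits)
        cache = {
            "E": E, "mf": mf, "msum": msum, "ctx_cache": ctx_cache,
            "att_caches": att_caches, "pooled": pooled, "probs": probs,
            "ids": ids, "mask": mask, "oovs": oovs,
        }
        return probs, cache

    def forward(self, seq: TokenSequence, train: bool = False) -> np.ndarray:
        """Class probabilities for one sequence (scalar array for binary)."""
        ids, mask, oovs, _ = self.make_batch([seq])
        probs, _ = self._forward(ids, mask, oovs, train, None)
        return probs[0, 0] if self.config.task_mode == "binary" else probs[0]

    # -------------------------------------------------------------- backward

    def loss_and_grads(self, ids, mask, oovs, labels, train=True, dropout_rng=None):
        cfg = self.config
        probs, cache = self._forward(ids, mask, oovs, train, dropout_rng)
        B = ids.shape[0]
        eps = 1e-12
        if cfg.task_mode == "multiclass":
            y = np.zeros_like(probs)
            y[np.arange(B), labels] = 1.0
            loss = float(-(y * np.log(probs + eps)).sum() / B)
            dlogits = (probs - y) / B
        else:
            y = labels.astype(probs.dtype).reshape(B, -1)
            if cfg.task_mode == "binary":
                y = y.reshape(B, 1)
            loss = float(
                -(y * np.log(probs + eps) + (1 - y) * np.log(1 - probs + eps)).sum() / (B * probs.shape[1])
            )
            dlogits = (probs - y) / (B * probs.shape[1])
        dlogits = dlogits.astype(probs.dtype)

        grads = {name: np.zeros_like(arr) for name, arr in self.param_items(trainable_only=True)}
        grads["head.W"] += cache["pooled"].T @ dlogits
        grads["head.b"] += dlogits.sum(axis=0)
        dpooled = dlogits @ self.head_W.T
        mf, msum = cache["mf"], cache["msum"]
        dX = dpooled[:, None, :] * (mf / msum)[..., None]
        for i in reversed(range(len(self.blocks))):
            g, dX = att.stacked_backward(cache["att_caches"][i], dX)
            for k, v in g.items():
                grads[f"att{i}.{k}"] += v
        if cfg.use_bilstm:
            gctx, dE = ctx.context_encode_backward(cache["ctx_cache"], dX)
            grads["ctx.proj_W"] += gctx["proj_W"]
            grads["ctx.proj_b"] += gctx["proj_b"]
            grads["ctx.fusion_logits"] += gctx["fusion_logits"]
            for lname in ("layer1", "layer2"):
                for d in ("fw", "bw"):
                    for k in ("W", "U", "b"):
                        grads[f"ctx.{lname}.{d}.{k}"] += gctx[lname][d][k]
        else:
            E = cache["E"]
            grads["ctx.proj_W"] += E.reshape(-1, E.shape[-1]).T @ dX.reshape(-1, dX.shape[-1])
            grads["ctx.proj_b"] += dX.sum(axis=(0, 1))
            dE = dX @ self.ctx.proj_W.T
        self._embed_backward(dE, ids, mask, oovs, grads)
        return loss, grads, probs

    # -------------------------------------------------------------- training

    def train(
        self,
        train_seqs: Sequence[TokenSequence],
        val_seqs: Optional[Sequence[TokenSequence]] = None,
    ) -> TrainingHistory:
        """Run the full training recipe; reproducible given the config seeds."""
        cfg = self.config
        if len(train_seqs) == 0:
            raise ValueError("empty training set")
        shuffle_rng = np.random.default_rng(cfg.seed_shuffle)
        dropout_rng = np.random.default_rng(cfg.seed_dropout)
        n = len(train_seqs)
        steps_per_epoch = int(np.ceil(n / cfg.batch_size))
        total_steps = cfg.epochs * steps_per_epoch
        names = [name for name, _ in self.param_items(trainable_only=True)]
        arrays = dict(self.param_items(trainable_only=True))
        m_state = {k: np.zeros_like(v) for k, v in arrays.items()}
        v_state = {k: np.zeros_like(v) for k, v in arrays.items()}
        beta1, beta2, adam_eps = 0.9, 0.999, 1e-8
        history = TrainingHistory()
        step = 0
        for _epoch in range(cfg.epochs):
            order = shuffle_rng.permutation(n)
            for start in range(0, n, cfg.batch_size):
                step += 1
                batch = [train_seqs[i] for i in order[start : start + cfg.batch_size]]
                ids, mask, oovs, labels = self.make_batch(batch)
                if labels is None:
                    raise ValueError("training sequences must carry labels")
                loss, grads, _ = self.loss_and_grads(ids, mask, oovs, labels, True, dropout_rng)
                if not np.isfinite(loss):
                    raise RuntimeError(f"NaN/inf loss at step {step}; aborting training")
                if cfg.use_ewma:
                    for i, buf in enumerate(self.ewma_buffers):
                        for k in ("wq", "wk"):
                            buf[k][...] = att.ewma_update(buf[k], grads[f"att{i}.{k}"], cfg.rho)
                            grads[f"att{i}.{k}"] = buf[k].copy()
                lr = lr_schedule(step, total_steps, cfg.learning_rate, cfg.warmup_fraction)
                for name in names:
                    g = grads[name]
                    m_state[name][...] = beta1 * m_state[name] + (1 - beta1) * g
                    v_state[name][...] = beta2 * v_state[name] + (1 - beta2) * g * g
                    mhat = m_state[name] / (1 - beta1**step)
                    vhat = v_state[name] / (1 - beta2**step)
                    arrays[name] -= (lr * mhat / (np.sqrt(vhat) + adam_eps)).astype(arrays[name].dtype)
                self.tables.word_table[0] = 0.0  # padding row stays frozen
                history.losses.append(loss)
                history.lrs.append(lr)
            if val_seqs:
                from .evaluation import confusion, precision_recall_f1

                y_true = np.array([s.label for s in val_seqs])
                y_pred = self.predict(val_seqs)
                metrics = precision_recall_f1(confusion(y_true, y_pred, positive_class=1))
                history.val_metrics.append(
                    {"precision": metrics.precision, "recall": metrics.recall, "f1": metrics.f1}
                )
        return history

    # ------------------------------------------------------------- inference

    def predict_proba(self, seqs: Sequence[TokenSequence]) -> np.ndarray:
        if len(seqs) == 0:
            return np.zeros((0, self.config.n_outputs))
        out = []
        for start in range(0, len(seqs), self.config.batch_size):
            chunk = seqs[start : start + self.config.batch_size]
            ids, mask, oovs, _ = self.make_batch(chunk)
            probs, _ = self._forward(ids, mask, oovs, False, None)
            out.append(probs)
        return np.concatenate(out, axis=0)

    def predict(self, seqs: Sequence[TokenSequence]) -> np.ndarray:
        """Hard labels; probability >= threshold is positive, argmax for multiclass."""
        probs = self.predict_proba(seqs)
        if self.config.task_mode == "multiclass":
            return probs.argmax(axis=1)
        if self.config.task_mode == "binary":
            return (probs[:, 0] >= self.config.threshold).astype(np.int64)
        return (probs >= self.config.threshold).astype(np.int64)

    # ----------------------------------------------------------- persistence

    def save(self, path: str) -> None:
        arrays = {name: arr for name, arr in self.param_items(trainable_only=False)}
        arrays["emb.pos"] = self.tables.position_table
        for i, buf in enumerate(self.ewma_buffers):
            arrays[f"ewma{i}.wq"] = buf["wq"]
            arrays[f"ewma{i}.wk"] = buf["wk"]
        np.savez(path, __config__=np.frombuffer(json.dumps(asdict(self.config)).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path: str, vocab: Vocabulary) -> "TextClassifier":
        with np.load(path) as data:
            config = ModelConfig(**json.loads(bytes(data["__config__"]).decode()))
            model = cls(config, vocab)
            for name, arr in model.param_items(trainable_only=False):
                arr[...] = data[name]
            model.tables.position_table[...] = data["emb.pos"]
            for i, buf in enumerate(model.ewma_buffers):
                buf["wq"][...] = data[f"ewma{i}.wq"]
                buf["wk"][...] = data[f"ewma{i}.wk"]
        return model
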