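"""The multitask screening network and its model/results wrapper.

Architecture (shared trunk -> task heads):

    token + position embeddings
      -> N post-LN transformer encoder layers
      -> extra multihead self-attention block (residual + layer norm)
      -> dual-feature fusion: concat(pooled [CLS] state, masked mean of
         token states)                       f_combined, length 2d
      -> MLP 2d -> 512 -> 256 with ReLU      f_enhanced  (non-negative)
      -> four heads: PHQ-9/GAD-7 score regression (linear scalars) and
         PHQ-9/GAD-7 severity classification (softmax over 3 levels)

The shared trunk parameters are the vehicle of inductive transfer between
the depression and anxiety tasks; the heads are task-specific.

``MultitaskTextModel`` wraps corpus + architecture + objective the way
statsmodels wraps data + design: construct it from a split corpus, call
``fit`` and receive a ``MultitaskResults`` carrying the fitted parameters,
training history, EMA shadow and evaluation methods.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .autodiff import Tensor, concat, no_grad, softmax
from .corpus import (
    GAD7_MAX,
    PHQ9_MAX,
    SplitDataset,
    Tokenizer,
    WhitespaceTokenizer,
    pad_batch,
    stratified_split,
    tokenize,
)
from .losses import LossWeights, compute_class_weights
from .nn import Embedding, Linear, LayerNorm, Module, MultiHeadSelfAttention, TransformerLayer, dropout

__all__ = [
    "EncoderSpec",
    "TaskOutputs",
    "ParameterPartition",
    "attention",
    "MultitaskNetwork",
    "MultitaskTextModel",
    "MultitaskResults",
]


@dataclass
class EncoderSpec:
    """Encoder hyperparameters. The ``pretrained`` kind mirrors the
    standard base configuration (12 layers, 12 heads, d=768); the
    ``tiny_random`` kind is a from-scratch encoder sized so full training
    runs in seconds on a CPU."""

    kind: str = "tiny_random"
    n_layers: int = 2
    n_heads: int = 2
    hidden_dim: int = 32
    max_len: int = 96
    vocab_size: int = 200
    ff_hidden: int | None = None
    mlp_hidden: int = 512
    mlp_out: int = 256
    extra_attention_blocks: int = 1

    def __post_init__(self):
        if self.kind == "pretrained":
            self.n_layers, self.n_heads, self.hidden_dim = 12, 12, 768
        if self.hidden_dim % self.n_heads != 0:
            raise ValueError("hidden_dim must be divisible by n_heads")
        if self.ff_hidden is None:
            self.ff_hidden = 4 * self.hidden_dim

    @classmethod
    def tiny(cls, vocab_size: int, **kw) -> "EncoderSpec":
        return cls(kind="tiny_random", vocab_size=vocab_size, **kw)


@dataclass
class TaskOutputs:
    """Four-headed prediction for a batch: two continuous scores and two
    severity probability simplexes."""

    y_phq_reg: np.ndarray
    y_gad_reg: np.ndarray
    y_phq_cls: np.ndarray
    y_gad_cls: np.ndarray

    def clamped(self) -> "TaskOutputs":
        """Regression outputs clamped to the scale ranges (reporting only;
        the training loss sees raw outputs)."""
        return TaskOutputs(
            y_phq_reg=np.clip(self.y_phq_reg, 0, PHQ9_MAX),
            y_gad_reg=np.clip(self.y_gad_reg, 0, GAD7_MAX),
            y_phq_cls=self.y_phq_cls,
            y_gad_cls=self.y_gad_cls,
        )


@dataclass
class ParameterPartition:
    shared: dict[str, Tensor]
    depression_head: dict[str, Tensor]
    anxiety_head: dict[str, Tensor]


def attention(q, k, v, d_k: int, mask: np.ndarray | None = None):
    """Scaled dot-product attention softmax(QK^T / sqrt(d_k)) V.

    Accepts Tensors or arrays (any batch shape with trailing (L, d_k) /
    (L, d_v)); each attention row is a convex combination of V rows.
    """
    if d_k <= 0:
        raise ValueError("d_k must be positive")
    q = q if isinstance(q, Tensor) else Tensor(np.asarray(q, dtype=float))
    k = k if isinstance(k, Tensor) else Tensor(np.asarray(k, dtype=float))
    v = v if isinstance(v, Tensor) else Tensor(np.asarray(v, dtype=float))
    scores = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(d_k))
    if mask is not None:
        bias = (1.0 - np.asarray(mask, dtype=float)) * -1e9
        scores = scores + Tensor(np.broadcast_to(bias[..., None, :], scores.shape).copy())
    return softmax(scores, axis=-1) @ v


class _ExtraAttentionBlock(Module):
    """Self-attention block appended after the encoder: MHA + residual +
    layer norm (no feed-forward sublayer)."""

    def __init__(self, dim: int, n_heads: int, rng):
        super().__init__()
        self.attn = MultiHeadSelfAttention(dim, n_heads, rng)
        self.ln = LayerNorm(dim)

    def __call__(self, h, mask, p_drop=0.0, rng=None, keep=True):
        if not keep:
            return h
        a = self.attn(h, mask, attn_dropout=p_drop, rng=rng)
        return self.ln(h + dropout(a, p_drop, rng, self.training))


class MultitaskNetwork(Module):
    def __init__(self, spec: EncoderSpec, seed: int = 0):
        super().__init__()
        self.spec = spec
        rng = np.random.default_rng(seed)
        d = spec.hidden_dim
        self.tok_emb = Embedding(spec.vocab_size, d, rng)
        self.pos_emb = Embedding(spec.max_len, d, rng)
        self.emb_ln = LayerNorm(d)
        for i in range(spec.n_layers):
            setattr(self, f"layer{i}", TransformerLayer(d, spec.n_heads, spec.ff_hidden, rng))
        for i in range(spec.extra_attention_blocks):
            setattr(self, f"extra{i}", _ExtraAttentionBlock(d, spec.n_heads, rng))
        self.mlp1 = Linear(2 * d, spec.mlp_hidden, rng)
        self.mlp2 = Linear(spec.mlp_hidden, spec.mlp_out, rng)
        self.phq_reg = Linear(spec.mlp_out, 1, rng)
        self.gad_reg = Linear(spec.mlp_out, 1, rng)
        self.phq_cls = Linear(spec.mlp_out, 3, rng)
        self.gad_cls = Linear(spec.mlp_out, 3, rng)

    # -- spec operations, exposed individually for testing ------------------

    def encode(
        self,
        ids: np.ndarray,
        mask: np.ndarray,
        p_drop: float = 0.0,
        rng=None,
        layer_keep: np.ndarray | None = None,
    ) -> Tensor:
        """Per-token hidden states (B, L, d). ``layer_keep`` is the
        stochastic-depth mask over the encoder layers' sub-blocks."""
        ids = np.asarray(ids)
        if ids.shape[1] > self.spec.max_len:
            raise ValueError(f"sequence length {ids.shape[1]} exceeds max_len {self.spec.max_len}")
        h = self.tok_emb(ids) + self.pos_emb.weight[np.arange(ids.shape[1])]
        h = self.emb_ln(h)
        h = dropout(h, p_drop, rng, self.training)
        for i in range(self.spec.n_layers):
            keep_attn = bool(layer_keep[2 * i]) if layer_keep is not None else True
            keep_ff = bool(layer_keep[2 * i + 1]) if layer_keep is not None else True
            h = getattr(self, f"layer{i}")(h, mask, p_drop, rng, keep_attn, keep_ff)
        for i in range(self.spec.extra_attention_blocks):
            h = getattr(self, f"extra{i}")(h, mask, p_drop, rng)
        return h

    @staticmethod
    def fuse(h: Tensor, mask: np.ndarray, pooled: Tensor) -> Tensor:
        """Dual-feature fusion: f_combined = concat(pooled, masked mean of
        token states), length 2d."""
        mask = np.asarray(mask, dtype=float)
        denom = mask.sum(axis=1, keepdims=True)
        if np.any(denom == 0):
            raise ValueError("all-zero attention mask")
        f_global = (h * Tensor(mask[:, :, None])).sum(axis=1) * Tensor(1.0 / denom)
        return concat([pooled, f_global], axis=-1)

    def enhance(self, f_combined: Tensor, p_drop: float = 0.0, rng=None) -> Tensor:
        """Two-layer MLP with ReLU at both layers: 2d -> 512 -> 256."""
        hidden = dropout(self.mlp1(f_combined).relu(), p_drop, rng, self.training)
        return self.mlp2(hidden).relu()

    def heads(self, f_enhanced: Tensor) -> dict[str, Tensor]:
        return {
            "phq_reg": self.phq_reg(f_enhanced)[:, 0],
            "gad_reg": self.gad_reg(f_enhanced)[:, 0],
            "phq_cls": softmax(self.phq_cls(f_enhanced), axis=-1),
            "gad_cls": softmax(self.gad_cls(f_enhanced), axis=-1),
        }

    # -- full passes ---------------------------------------------------------

    def forward(
        self,
        ids: np.ndarray,
        mask: np.ndarray,
        p_drop: float = 0.0,
        rng=None,
        layer_keep: np.ndarray | None = None,
    ) -> dict[str, Tensor]:
        h = self.encode(ids, mask, p_drop, rng, layer_keep)
        pooled = h[:, 0, :]  # raw [CLS] state (tiny-encoder convention)
        f_combined = self.fuse(h, mask, pooled)
        f_enhanced = self.enhance(f_combined, p_drop, rng)
        return self.heads(f_enhanced)

    def predict(self, ids: np.ndarray, mask: np.ndarray, clamp: bool = True) -> TaskOutputs:
        """Inference-mode prediction (no dropout, no graph)."""
        was_training = self.training
        self.eval()
        try:
            with no_grad():
                out = self.forward(ids, mask)
        finally:
            if was_training:
                self.train()
        res = TaskOutputs(
            y_phq_reg=out["phq_reg"].data.copy(),
            y_gad_reg=out["gad_reg"].data.copy(),
            y_phq_cls=out["phq_cls"].data.copy(),
            y_gad_cls=out["gad_cls"].data.copy(),
        )
        return res.clamped() if clamp else res

    def parameter_partition(self) -> ParameterPartition:
        shared, dep, anx = {}, {}, {}
        for name, p in self.parameters().items():
            if name.startswith("phq_"):
                dep[name] = p
            elif name.startswith("gad_"):
                anx[name] = p
            else:
                shared[name] = p
        return ParameterPartition(shared=shared, depression_head=dep, anxiety_head=anx)

    def fusion_and_head_parameters(self) -> dict[str, Tensor]:
        """Default scope of the explicit L2 term: fusion MLP + task heads
        (the optimizer's weight decay covers the encoder)."""
        return {
            n: p
            for n, p in self.parameters().items()
            if n.split(".")[0] in ("mlp1", "mlp2", "phq_reg", "gad_reg", "phq_cls", "gad_cls")
        }


# ---------------------------------------------------------------------------
# model / results wrappers
# ---------------------------------------------------------------------------

class MultitaskTextModel:
    """Joint PHQ-9/GAD-7 screening model over a split text corpus.

    Parameters
    ----------
    split : SplitDataset
        Train/validation/test partition of labeled records.
    tokenizer : Tokenizer, optional
        Fitted on the training texts when omitted.
    encoder_spec : EncoderSpec, optional
        Defaults to the tiny from-scratch encoder sized to the vocabulary.
    loss_weights : LossWeights, optional
        Class weights default to inverse-frequency weights computed from
        the training split actually used for fitting.
    """

    def __init__(
        self,
        split: SplitDataset,
        tokenizer: Tokenizer | None = None,
        encoder_spec: EncoderSpec | None = None,
        loss_weights: LossWeights | None = None,
        max_len: int = 96,
    ):
        self.split = split
        self.max_len = max_len
        if tokenizer is None:
            tokenizer = WhitespaceTokenizer.fit(r.text for r in split.train)
        self.tokenizer = tokenizer
        if encoder_spec is None:
            encoder_spec = EncoderSpec.tiny(vocab_size=tokenizer.vocab_size, max_len=max_len)
        else:
            encoder_spec.vocab_size = max(encoder_spec.vocab_size, tokenizer.vocab_size)
        self.encoder_spec = encoder_spec
        if loss_weights is None:
            loss_weights = LossWeights()
        if np.allclose(loss_weights.class_weights_phq, 1.0) and split.train:
            loss_weights.class_weights_phq = compute_class_weights(
                [r.phq9_severity for r in split.train]
            )
        if np.allclose(loss_weights.class_weights_gad, 1.0) and split.train:
            loss_weights.class_weights_gad = compute_class_weights(
                [r.gad7_severity for r in split.train]
            )
        self.loss_weights = loss_weights

    @classmethod
    def from_corpus(
        cls,
        corpus,
        ratios=(8, 1, 1),
        seed: int = 0,
        **kwargs,
    ) -> "MultitaskTextModel":
        return cls(stratified_split(corpus, ratios=ratios, seed=seed), **kwargs)

    # -- data plumbing -------------------------------------------------------

    def encode_records(self, records) -> tuple[np.ndarray, np.ndarray]:
        samples = [tokenize(r.text, self.tokenizer, self.max_len) for r in records]
        return pad_batch(samples, pad_id=self.tokenizer.pad_id)

    def fit(self, train_config=None, tasks: str = "both", seed: int | None = None) -> "MultitaskResults":
        """Train the network under the configured objective.

        ``tasks`` selects the multitask objective (``"both"``) or a
        single-task reduction (``"phq9"`` / ``"gad7"``): the other task's
        per-task loss weight is set to zero, which blocks its gradients.
        """
        from .training import TrainConfig, train as _train

        config = train_config or TrainConfig()
        if seed is not None:
            config = config.replace(seed=seed)
        network, ema, history = _train(self, config, tasks=tasks)
        return MultitaskResults(self, network, ema, history, config, tasks)


class MultitaskResults:
    """Fitted-model container: best-validation parameters, EMA shadow,
    training history, and evaluation/reporting methods."""

    def __init__(self, model: MultitaskTextModel, network: MultitaskNetwork, ema_state, history, config, tasks="both"):
        self.model = model
        self.network = network
        self.ema_state = ema_state
        self.history = history
        self.config = config
        self.tasks = tasks

    def predict_records(self, records, use_ema: bool = False) -> TaskOutputs:
        net = self.ema_network() if use_ema else self.network
        ids, mask = self.model.encode_records(records)
        return net.predict(ids, mask)

    def predict_texts(self, texts, use_ema: bool = False) -> TaskOutputs:
        from .corpus import LabeledText

        records = [LabeledText(record_id=f"q{i}", text=t, phq9=0, gad7=0) for i, t in enumerate(texts)]
        return self.predict_records(records, use_ema=use_ema)

    def ema_network(self) -> MultitaskNetwork:
        net = MultitaskNetwork(self.model.encoder_spec, seed=0)
        net.load_state_dict(self.ema_state.shadow)
        net.eval()
        return net

    def evaluate(self, records=None, use_ema: bool = False):
        from .evaluation import evaluate_records

        if records is None:
            records = self.model.split.test
        return evaluate_records(self, records, use_ema=use_ema)

    def summary(self) -> str:
        report = self.evaluate()
        lines = [
            "Multitask text screening model",
            "=" * 66,
            f"encoder: {self.model.encoder_spec.kind} "
            f"({self.model.encoder_spec.n_layers} layers, d={self.model.encoder_spec.hidden_dim})",
            f"parameters: {self.network.n_parameters():,}   tasks: {self.tasks}",
            f"epochs run: {len(self.history.epochs)}   best epoch: {self.history.best_epoch}",
            "-" * 66,
            f"{'metric':<22}{'PHQ-9':>12}{'GAD-7':>12}",
        ]
        for name in ("mse", "rmse", "mae", "pearson_r", "r2", "auc", "accuracy", "f1_positive"):
            row = [getattr(report.phq9, name), getattr(report.gad7, name)]
            cells = "".join(f"{v:>12.3f}" if v == v else f"{'--':>12}" for v in row)
            lines.append(f"{name:<22}{cells}")
        lines.append("=" * 66)
        return "\n".join(lines)

    def save(self, directory: str | Path):
        """Checkpoint: parameter archive (.npz) + JSON sidecar describing
        the architecture and run configuration."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.savez(directory / "parameters.npz", **self.network.state_dict())
        np.savez(directory / "ema.npz", **self.ema_state.shadow)
        sidecar = {
            "encoder_spec": {**self.model.encoder_spec.__dict__},
            "tasks": self.tasks,
            "config": self.config.to_dict(),
            "vocab": getattr(self.model.tokenizer, "vocab", {}),
            "best_epoch": self.history.best_epoch,
        }
        (directory / "checkpoint.json").write_text(json.dumps(sidecar, ensure_ascii=False))
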