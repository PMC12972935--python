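"""Training protocol: AdamW with cosine annealing, the regularization
bundle (dropout, decoupled weight decay, stochastic depth, label smoothing,
gradient noise), early stopping on the validation mean screening F1,
per-step EMA parameter smoothing, and seed-based ensembling.

Every random stream (initialisation, batching, dropout, stochastic depth,
gradient noise) derives from the single run seed, so a run is reproducible
bit-for-bit in single-threaded mode.
"""

from __future__ import annotations

import copy
import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor
from .corpus import SCREEN_THRESHOLD, SEVERITY_LEVELS
from .losses import _one_task_ce, l2_penalty, total_loss
from .model import MultitaskNetwork, TaskOutputs

log = logging.getLogger(__name__)

_SEV_INDEX = {s: i for i, s in enumerate(SEVERITY_LEVELS)}


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters of the training protocol.

    The defaults describe the full protocol for fine-tuning a large
    pretrained encoder (peak learning rate 1e-5, dropout 0.5, 35 epochs).
    For from-scratch tiny encoders use :meth:`desk_scale`, which keeps the
    protocol but re-centres the optimisation constants on the from-scratch
    regime (higher learning rate, lighter dropout, fewer epochs).
    """

    epochs: int = 35
    batch_size: int = 58
    lr_max: float = 1e-5
    lr_min: float = 1e-6
    patience: int = 3
    dropout: float = 0.5
    weight_decay: float = 0.03
    stochastic_depth_rate: float = 0.1
    label_smoothing: float = 0.1
    grad_noise_scale: float = 1e-5
    ema_decay: float = 0.999
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.ema_decay < 1.0:
            raise ValueError("ema_decay must lie in [0, 1)")
        if self.lr_min > self.lr_max:
            raise ValueError("lr_min must not exceed lr_max")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")

    def replace(self, **kw) -> "TrainConfig":
        return dataclasses.replace(self, **kw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def desk_scale(cls, **overrides) -> "TrainConfig":
        base = dict(
            epochs=15,
            batch_size=32,
            lr_max=2e-3,
            lr_min=2e-4,
            dropout=0.1,
            ema_decay=0.95,
        )
        base.update(overrides)
        return cls(**base)


def cosine_lr(t: int, config: TrainConfig) -> float:
    """Cosine-annealed learning rate at epoch ``t`` (0-based, <= T):
    lr_min + (lr_max - lr_min)(1 + cos(t pi / T)) / 2."""
    T = config.epochs
    if not 0 <= t <= T:
        raise ValueError(f"epoch {t} outside [0, {T}]")
    return config.lr_min + 0.5 * (config.lr_max - config.lr_min) * (1.0 + np.cos(t * np.pi / T))


def inject_gradient_noise(grads: dict[str, np.ndarray], scale: float, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Add i.i.d. zero-mean Gaussian noise with standard deviation
    ``scale`` to every gradient entry."""
    if scale < 0:
        raise ValueError("noise scale must be non-negative")
    if scale == 0:
        return grads
    return {k: g + rng.normal(0.0, scale, size=g.shape) for k, g in grads.items()}


def stochastic_depth_mask(n_layers: int, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Keep mask over residual sub-blocks: entry 0 means the block is
    skipped (residual-only pass) this step. Training-time only; evaluation
    always runs full depth."""
    if not 0.0 <= rate < 1.0:
        raise ValueError("rate must lie in [0, 1)")
    return (rng.random(n_layers) >= rate).astype(np.int64)


@dataclass
class EMAState:
    """Exponential moving average of parameters:
    shadow <- decay * shadow + (1 - decay) * current."""

    shadow: dict[str, np.ndarray]
    decay: float
    step_count: int = 0


def ema_update(state: EMAState, current: dict[str, np.ndarray | Tensor]) -> EMAState:
    b = state.decay
    for name, value in current.items():
        data = value.data if isinstance(value, Tensor) else np.asarray(value, dtype=float)
        if name not in state.shadow:
            raise KeyError(f"unknown parameter {name}")
        if state.shadow[name].shape != data.shape:
            raise ValueError(f"shape mismatch for {name}")
        state.shadow[name] = b * state.shadow[name] + (1.0 - b) * data
    state.step_count += 1
    return state


@dataclass
class TrainHistory:
    epochs: list[int] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)
    train_loss: list[float] = field(default_factory=list)
    train_mse_phq: list[float] = field(default_factory=list)
    train_mse_gad: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_f1_phq: list[float] = field(default_factory=list)
    val_f1_gad: list[float] = field(default_factory=list)
    val_f1_mean: list[float] = field(default_factory=list)
    best_epoch: int = -1
    stopped_early: bool = False

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame({
            "epoch": self.epochs,
            "lr": self.lr,
            "train_loss": self.train_loss,
            "train_mse_phq": self.train_mse_phq,
            "train_mse_gad": self.train_mse_gad,
            "val_loss": self.val_loss,
            "val_f1_phq": self.val_f1_phq,
            "val_f1_gad": self.val_f1_gad,
            "val_f1_mean": self.val_f1_mean,
        })

    def to_csv(self, path):
        self.to_dataframe().to_csv(path, index=False)


def early_stop(monitored: list[float], patience: int) -> bool:
    """True iff the monitored metric has not strictly improved on its best
    value for ``patience`` consecutive epochs."""
    if not monitored:
        return False
    best, since = -np.inf, 0
    for v in monitored:
        if v > best:
            best, since = v, 0
        else:
            since += 1
    return since >= patience


class AdamW:
    """Adam with decoupled weight decay."""

    def __init__(self, params: dict[str, Tensor], weight_decay: float = 0.0,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.weight_decay = weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def step(self, lr: float, grads: dict[str, np.ndarray]):
        self.t += 1
        for k, p in self.params.items():
            g = grads.get(k)
            if g is None:
                continue
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            p.data = p.data - lr * (mhat / (np.sqrt(vhat) + self.eps) + self.weight_decay * p.data)


def _screen_f1(pred_scores: np.ndarray, true_scores: np.ndarray) -> float:
    """Positive-class F1 of the binary screen (score >= 10)."""
    p = pred_scores >= SCREEN_THRESHOLD
    t = true_scores >= SCREEN_THRESHOLD
    tp = int(np.sum(p & t))
    denom = 2 * tp + int(np.sum(p & ~t)) + int(np.sum(~p & t))
    return 2 * tp / denom if denom else 0.0


def train(model, config: TrainConfig, tasks: str = "both"):
    """Run the full protocol on ``model`` (a MultitaskTextModel).

    Returns ``(network, ema_state, history)`` where ``network`` carries the
    best-validation checkpoint. ``tasks`` in {"both", "phq9", "gad7"}
    selects the multitask objective or a single-task reduction (the other
    task's per-task weight is zeroed, blocking its gradient path).
    """
    if tasks not in ("both", "phq9", "gad7"):
        raise ValueError("tasks must be 'both', 'phq9' or 'gad7'")
    split = model.split
    if not split.train or not split.validation:
        raise ValueError("train and validation splits must be non-empty")

    master = np.random.default_rng(config.seed)
    seeds = master.integers(0, 2**31 - 1, size=5)
    rng_batch = np.random.default_rng(seeds[0])
    rng_drop = np.random.default_rng(seeds[1])
    rng_depth = np.random.default_rng(seeds[2])
    rng_noise = np.random.default_rng(seeds[3])

    network = MultitaskNetwork(model.encoder_spec, seed=int(seeds[4]))
    weights = copy.deepcopy(model.loss_weights)
    weights = dataclasses.replace(weights, label_smoothing=config.label_smoothing)
    lam_d = weights.lambda_depression if tasks in ("both", "phq9") else 0.0
    lam_a = weights.lambda_anxiety if tasks in ("both", "gad7") else 0.0

    ids_tr, mask_tr = model.encode_records(split.train)
    phq_tr = np.array([r.phq9 for r in split.train], dtype=float)
    gad_tr = np.array([r.gad7 for r in split.train], dtype=float)
    sev_phq_tr = np.array([_SEV_INDEX[r.phq9_severity] for r in split.train])
    sev_gad_tr = np.array([_SEV_INDEX[r.gad7_severity] for r in split.train])
    ids_va, mask_va = model.encode_records(split.validation)
    phq_va = np.array([r.phq9 for r in split.validation], dtype=float)
    gad_va = np.array([r.gad7 for r in split.validation], dtype=float)

    optimizer = AdamW(network.parameters(), weight_decay=config.weight_decay)
    ema = EMAState(shadow=network.state_dict(), decay=config.ema_decay)
    history = TrainHistory()
    best_metric, best_state, since_best = -np.inf, network.state_dict(), 0
    n = len(split.train)
    n_blocks = 2 * model.encoder_spec.n_layers

    for epoch in range(config.epochs):
        lr = cosine_lr(epoch, config)
        network.train()
        order = rng_batch.permutation(n)
        ep_loss, ep_se_phq, ep_se_gad = 0.0, 0.0, 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start: start + config.batch_size]
            keep = stochastic_depth_mask(n_blocks, config.stochastic_depth_rate, rng_depth)
            out = network.forward(
                ids_tr[idx], mask_tr[idx], p_drop=config.dropout, rng=rng_drop, layer_keep=keep
            )
            err_p = out["phq_reg"] - Tensor(phq_tr[idx])
            err_g = out["gad_reg"] - Tensor(gad_tr[idx])
            reg = lam_d * (err_p * err_p).mean() + lam_a * (err_g * err_g).mean()
            cls = lam_d * _one_task_ce(
                out["phq_cls"], sev_phq_tr[idx], weights.class_weights_phq, weights.label_smoothing
            ) + lam_a * _one_task_ce(
                out["gad_cls"], sev_gad_tr[idx], weights.class_weights_gad, weights.label_smoothing
            )
            l2 = l2_penalty(network.fusion_and_head_parameters(), weights.lambda_l2)
            loss = total_loss(reg, cls, l2, weights)
            if not np.isfinite(loss.data):
                raise RuntimeError(f"training diverged at epoch {epoch}: loss={loss.data}")
            network.zero_grad()
            loss.backward()
            grads = {
                k: p.grad for k, p in network.parameters().items() if p.grad is not None
            }
            grads = inject_gradient_noise(grads, config.grad_noise_scale, rng_noise)
            optimizer.step(lr, grads)
            ema_update(ema, network.parameters())
            ep_loss += float(loss.data) * len(idx)
            ep_se_phq += float(np.sum((out["phq_reg"].data - phq_tr[idx]) ** 2))
            ep_se_gad += float(np.sum((out["gad_reg"].data - gad_tr[idx]) ** 2))

        val_out = network.predict(ids_va, mask_va)
        f1_phq = _screen_f1(val_out.y_phq_reg, phq_va)
        f1_gad = _screen_f1(val_out.y_gad_reg, gad_va)
        if tasks == "phq9":
            monitored = f1_phq
        elif tasks == "gad7":
            monitored = f1_gad
        else:
            monitored = 0.5 * (f1_phq + f1_gad)
        val_mse = float(
            lam_d * np.mean((val_out.y_phq_reg - phq_va) ** 2)
            + lam_a * np.mean((val_out.y_gad_reg - gad_va) ** 2)
        )

        history.epochs.append(epoch)
        history.lr.append(lr)
        history.train_loss.append(ep_loss / n)
        history.train_mse_phq.append(ep_se_phq / n)
        history.train_mse_gad.append(ep_se_gad / n)
        history.val_loss.append(val_mse)
        history.val_f1_phq.append(f1_phq)
        history.val_f1_gad.append(f1_gad)
        history.val_f1_mean.append(monitored)
        log.info("epoch %d lr=%.2e loss=%.4f val F1=%.3f", epoch, lr, ep_loss / n, monitored)

        if monitored > best_metric:
            best_metric, since_best = monitored, 0
            best_state = network.state_dict()
            history.best_epoch = epoch
        else:
            since_best += 1
        if since_best >= config.patience:
            history.stopped_early = True
            log.info("early stopping at epoch %d (best epoch %d)", epoch, history.best_epoch)
            break

    network.load_state_dict(best_state)
    network.eval()
    return network, ema, history


def ensemble_predict(networks, ids: np.ndarray, mask: np.ndarray, weights=None) -> TaskOutputs:
    """Weighted-average ensemble: regression outputs are averaged with the
    given weights; classification simplexes are averaged then renormalized."""
    if not networks:
        raise ValueError("empty model list")
    if weights is None:
        weights = np.full(len(networks), 1.0 / len(networks))
    weights = np.asarray(weights, dtype=float)
    if np.any(weights < 0) or abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError("weights must be non-negative and sum to 1")
    outs = [net.predict(ids, mask) for net in networks]
    phq_cls = sum(w * o.y_phq_cls for w, o in zip(weights, outs))
    gad_cls = sum(w * o.y_gad_cls for w, o in zip(weights, outs))
    phq_cls = phq_cls / phq_cls.sum(axis=-1, keepdims=True)
    gad_cls = gad_cls / gad_cls.sum(axis=-1, keepdims=True)
    return TaskOutputs(
        y_phq_reg=sum(w * o.y_phq_reg for w, o in zip(weights, outs)),
        y_gad_reg=sum(w * o.y_gad_reg for w, o in zip(weights, outs)),
        y_phq_cls=phq_cls,
        y_gad_cls=gad_cls,
    )


def train_ensemble(model, config: TrainConfig, n_members: int = 3, tasks: str = "both"):
    """Train ``n_members`` networks from distinct seeds derived from the
    run seed; returns the list of fitted networks."""
    members = []
    for i in range(n_members):
        net, _, _ = train(model, config.replace(seed=config.seed + 1000 * i), tasks=tasks)
        members.append(net)
    return members
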