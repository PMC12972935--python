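"""The multitask objective.

Total loss = alpha * L_reg + beta * L_cls + gamma * L_l2, where

* ``L_reg`` is the mean over samples of the summed squared errors of the
  two score regressions (PHQ-9, GAD-7),
* ``L_cls`` is a class-weighted, label-smoothed cross-entropy summed over
  the two 3-class severity tasks (weights w_c = N / (N_c * C) computed from
  training-set class counts),
* ``L_l2`` is an explicit L2 penalty over a configurable parameter subset
  (by default the task heads and fusion MLP; the optimizer's decoupled
  weight decay covers the encoder).

The defaults beta = 6.0 >> alpha = 0.3 deliberately bias the shared
representation toward severity categorisation over exact score regression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor
from .corpus import SEVERITY_LEVELS

log = logging.getLogger(__name__)

_PROB_FLOOR = 1e-12


@dataclass
class LossWeights:
    alpha: float = 0.3            # regression weight
    beta: float = 6.0             # classification weight
    gamma: float = 0.01           # weight of the explicit L2 term
    lambda_l2: float = 0.01       # coefficient inside the L2 term
    lambda_depression: float = 1.0
    lambda_anxiety: float = 1.0
    class_weights_phq: np.ndarray = field(default_factory=lambda: np.ones(3))
    class_weights_gad: np.ndarray = field(default_factory=lambda: np.ones(3))
    label_smoothing: float = 0.1

    def __post_init__(self):
        for name in ("alpha", "beta", "gamma", "lambda_l2", "lambda_depression", "lambda_anxiety"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.label_smoothing < 1.0:
            raise ValueError("label_smoothing must lie in [0, 1)")
        self.class_weights_phq = np.asarray(self.class_weights_phq, dtype=float)
        self.class_weights_gad = np.asarray(self.class_weights_gad, dtype=float)
        for w in (self.class_weights_phq, self.class_weights_gad):
            if np.any(w <= 0):
                raise ValueError("class weights must be strictly positive")


def compute_class_weights(labels, n_classes: int = 3) -> np.ndarray:
    """Inverse-frequency class weights w_c = N / (N_c * C).

    The identity sum_c N_c * w_c = N holds exactly. An absent class gets a
    weight computed against N_c = 1 (with a warning) to avoid division by
    zero; it never contributes to the loss since no sample carries it.
    """
    labels = list(labels)
    if not labels:
        raise ValueError("labels must be non-empty")
    if isinstance(labels[0], str):
        index = {s: i for i, s in enumerate(SEVERITY_LEVELS)}
        labels = [index[l] for l in labels]
    counts = np.bincount(np.asarray(labels, dtype=int), minlength=n_classes).astype(float)
    n = float(len(labels))
    empty = counts == 0
    if empty.any():
        log.warning("class(es) %s absent; weight computed against N_c=1", np.nonzero(empty)[0])
        counts[empty] = 1.0
    return n / (counts * n_classes)


def regression_loss(preds_phq, preds_gad, targets_phq, targets_gad):
    """Mean over samples of (e_PHQ^2 + e_GAD^2). Accepts Tensors or arrays;
    returns a Tensor when any input is a Tensor."""
    parts = []
    for p, t in ((preds_phq, targets_phq), (preds_gad, targets_gad)):
        t = Tensor(np.asarray(t, dtype=float)) if not isinstance(t, Tensor) else t
        p = p if isinstance(p, Tensor) else Tensor(np.asarray(p, dtype=float))
        if p.shape != t.shape:
            raise ValueError(f"prediction/target length mismatch: {p.shape} vs {t.shape}")
        err = p - t
        parts.append((err * err).mean())
    return parts[0] + parts[1]


def _one_task_ce(probs, labels, class_weights, smoothing: float):
    p = probs if isinstance(probs, Tensor) else Tensor(np.asarray(probs, dtype=float))
    labels = np.asarray(labels, dtype=int)
    n, C = p.shape
    if labels.shape[0] != n:
        raise ValueError("probs/labels length mismatch")
    onehot = np.eye(C)[labels]
    smoothed = (1.0 - smoothing) * onehot + smoothing / C
    w = np.asarray(class_weights, dtype=float)[None, :]
    if np.any(p.data <= _PROB_FLOOR):
        log.warning("probabilities at or below %.0e clipped in cross-entropy", _PROB_FLOOR)
    logp = p.clip_min(_PROB_FLOOR).log()
    return -(Tensor(w * smoothed) * logp).sum() * (1.0 / n)


def classification_loss(probs_phq, probs_gad, labels_phq, labels_gad, weights: LossWeights):
    """Weighted, label-smoothed cross-entropy summed over both severity
    tasks: -(1/N) sum_i sum_c w_c * y~_c log p_c per task."""

    s = weights.label_smoothing
    return _one_task_ce(probs_phq, labels_phq, weights.class_weights_phq, s) + _one_task_ce(
        probs_gad, labels_gad, weights.class_weights_gad, s
    )


def l2_penalty(parameters, lambda_l2: float):
    """lambda * sum of squared entries over the given parameter collection."""
    if isinstance(parameters, dict):
        parameters = parameters.values()
    total = None
    for p in parameters:
        p = p if isinstance(p, Tensor) else Tensor(np.asarray(p, dtype=float))
        term = (p * p).sum()
        total = term if total is None else total + term
    if total is None:
        return Tensor(0.0)
    return total * lambda_l2


def total_loss(reg, cls, l2, weights: LossWeights):
    """alpha * L_reg + beta * L_cls + gamma * L_l2."""
    return weights.alpha * reg + weights.beta * cls + weights.gamma * l2
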