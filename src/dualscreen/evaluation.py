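"""Evaluation metrics and the component-toggle ablation harness.

Regression metrics (MSE/RMSE/MAE/Pearson r/R^2), binary screening metrics
computed from 2x2 confusion matrices (orientation rows = true
{negative, positive}, columns = predicted), rank-based AUC, severity-
stratified 3-class metrics, and an ablation runner that retrains variant
models with identical data and seeds and reports deltas against the full
model.

Undefined metrics (zero denominators, constant truths, single-class AUC)
are reported as NaN and flagged by name rather than coerced to 0.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.stats import rankdata

from .corpus import SCREEN_THRESHOLD, SEVERITY_LEVELS

log = logging.getLogger(__name__)

_SEV_INDEX = {s: i for i, s in enumerate(SEVERITY_LEVELS)}


# ---------------------------------------------------------------------------
# confusion matrices and binary metrics
# ---------------------------------------------------------------------------

@dataclass
class ConfusionMatrix2:
    """2x2 confusion counts, [[tn, fp], [fn, tp]]."""

    tn: int
    fp: int
    fn: int
    tp: int

    def __post_init__(self):
        for v in (self.tn, self.fp, self.fn, self.tp):
            if v < 0:
                raise ValueError("counts must be non-negative")
        if self.total < 1:
            raise ValueError("confusion matrix must contain at least one count")

    @property
    def total(self) -> int:
        return self.tn + self.fp + self.fn + self.tp

    @classmethod
    def from_matrix(cls, m) -> "ConfusionMatrix2":
        m = np.asarray(m, dtype=int)
        if m.shape != (2, 2):
            raise ValueError("expected a 2x2 matrix")
        return cls(tn=int(m[0, 0]), fp=int(m[0, 1]), fn=int(m[1, 0]), tp=int(m[1, 1]))

    @classmethod
    def from_predictions(cls, pred: np.ndarray, true: np.ndarray) -> "ConfusionMatrix2":
        pred = np.asarray(pred, dtype=bool)
        true = np.asarray(true, dtype=bool)
        return cls(
            tn=int(np.sum(~true & ~pred)),
            fp=int(np.sum(~true & pred)),
            fn=int(np.sum(true & ~pred)),
            tp=int(np.sum(true & pred)),
        )


@dataclass
class BinaryMetrics:
    accuracy: float
    precision: float
    recall: float           # sensitivity
    specificity: float
    f1_positive: float
    f1_macro: float
    undefined: set = field(default_factory=set)

    @property
    def sensitivity(self) -> float:
        return self.recall


def _ratio(num: float, den: float, name: str, undefined: set) -> float:
    if den == 0:
        undefined.add(name)
        return float("nan")
    return num / den


def binary_metrics(cm: ConfusionMatrix2) -> BinaryMetrics:
    """Standard screening metrics from a 2x2 matrix. ``f1_macro`` is the
    mean of the positive- and negative-class F1 scores; ``f1_positive`` is
    the positive class alone."""
    undef: set = set()
    tn, fp, fn, tp = cm.tn, cm.fp, cm.fn, cm.tp
    precision = _ratio(tp, tp + fp, "precision", undef)
    recall = _ratio(tp, tp + fn, "recall", undef)
    specificity = _ratio(tn, tn + fp, "specificity", undef)
    f1_pos = _ratio(2 * tp, 2 * tp + fp + fn, "f1_positive", undef)
    f1_neg = _ratio(2 * tn, 2 * tn + fp + fn, "f1_negative", undef)
    return BinaryMetrics(
        accuracy=(tp + tn) / cm.total,
        precision=precision,
        recall=recall,
        specificity=specificity,
        f1_positive=f1_pos,
        f1_macro=0.5 * (f1_pos + f1_neg),
        undefined=undef,
    )


def auc(scores, labels) -> float:
    """Pairwise-concordance AUC (ties count 1/2), equal to trapezoidal ROC
    integration. NaN when only one class is present."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        log.warning("AUC undefined: single-class labels")
        return float("nan")
    ranks = rankdata(scores)
    return (ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


# ---------------------------------------------------------------------------
# regression metrics
# ---------------------------------------------------------------------------

@dataclass
class RegressionMetrics:
    mse: float
    rmse: float
    mae: float
    pearson_r: float
    r2: float
    undefined: set = field(default_factory=set)


def regression_metrics(preds, truths) -> RegressionMetrics:
    preds = np.asarray(preds, dtype=float)
    truths = np.asarray(truths, dtype=float)
    if preds.shape != truths.shape or preds.size < 2:
        raise ValueError("preds and truths must have equal length >= 2")
    undef: set = set()
    err = preds - truths
    mse = float(np.mean(err**2))
    ss_tot = float(np.sum((truths - truths.mean()) ** 2))
    if ss_tot == 0 or np.std(preds) == 0:
        if ss_tot == 0:
            undef.update({"pearson_r", "r2"})
            r = r2 = float("nan")
        else:
            undef.add("pearson_r")
            r = float("nan")
            r2 = 1.0 - float(np.sum(err**2)) / ss_tot
    else:
        r = float(np.corrcoef(preds, truths)[0, 1])
        r2 = 1.0 - float(np.sum(err**2)) / ss_tot
    return RegressionMetrics(
        mse=mse,
        rmse=float(np.sqrt(mse)),
        mae=float(np.mean(np.abs(err))),
        pearson_r=r,
        r2=r2,
        undefined=undef,
    )


# ---------------------------------------------------------------------------
# severity-stratified (3-class) metrics
# ---------------------------------------------------------------------------

def multiclass_confusion(preds, truths) -> tuple[np.ndarray, dict]:
    """3x3 severity confusion matrix (rows = true, columns = predicted) and
    one-vs-rest per-stratum metrics plus overall accuracy."""
    p = np.array([_SEV_INDEX[x] if isinstance(x, str) else int(x) for x in preds])
    t = np.array([_SEV_INDEX[x] if isinstance(x, str) else int(x) for x in truths])
    if p.shape != t.shape:
        raise ValueError("length mismatch")
    m = np.zeros((3, 3), dtype=int)
    np.add.at(m, (t, p), 1)
    per: dict[str, dict[str, float]] = {}
    for c, name in enumerate(SEVERITY_LEVELS):
        cm = ConfusionMatrix2(
            tp=int(m[c, c]),
            fn=int(m[c].sum() - m[c, c]),
            fp=int(m[:, c].sum() - m[c, c]),
            tn=int(m.sum() - m[c].sum() - m[:, c].sum() + m[c, c]),
        )
        b = binary_metrics(cm)
        per[name] = {
            "n": int(m[c].sum()),
            "accuracy": (cm.tp + cm.tn) / cm.total,
            "precision": b.precision,
            "recall": b.recall,
            "f1": b.f1_positive,
            "specificity": b.specificity,
        }
    per["overall_accuracy"] = float(np.trace(m) / m.sum())
    return m, per


# ---------------------------------------------------------------------------
# full report
# ---------------------------------------------------------------------------

@dataclass
class TaskMetrics:
    mse: float
    rmse: float
    mae: float
    pearson_r: float
    r2: float
    auc: float
    accuracy: float
    precision: float
    recall: float
    specificity: float
    f1_positive: float
    f1_macro: float
    confusion2: ConfusionMatrix2 = None
    severity_confusion: np.ndarray = None
    severity_metrics: dict = None


@dataclass
class MetricsReport:
    phq9: TaskMetrics
    gad7: TaskMetrics
    n: int

    def to_dict(self) -> dict:
        def task(tm: TaskMetrics) -> dict:
            d = {
                k: getattr(tm, k)
                for k in (
                    "mse", "rmse", "mae", "pearson_r", "r2", "auc", "accuracy",
                    "precision", "recall", "specificity", "f1_positive", "f1_macro",
                )
            }
            d["confusion2"] = [[tm.confusion2.tn, tm.confusion2.fp], [tm.confusion2.fn, tm.confusion2.tp]]
            d["severity_confusion"] = tm.severity_confusion.tolist()
            d["severity_metrics"] = tm.severity_metrics
            return d

        return {"n": self.n, "phq9": task(self.phq9), "gad7": task(self.gad7)}

    def to_json(self, path: str | Path):
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, allow_nan=True, default=float))

    def to_frame(self):
        import pandas as pd

        rows = {}
        for scale in ("phq9", "gad7"):
            tm = getattr(self, scale)
            rows[scale] = {
                k: getattr(tm, k)
                for k in (
                    "mse", "rmse", "mae", "pearson_r", "r2", "auc", "accuracy",
                    "precision", "recall", "specificity", "f1_positive", "f1_macro",
                )
            }
        return pd.DataFrame(rows)


def metrics_from_predictions(pred_phq, pred_gad, cls_phq, cls_gad, true_phq, true_gad) -> MetricsReport:
    """Build a full report from continuous predictions, 3-class severity
    probability vectors and true scores. The binary screen uses the
    regression prediction against the clinical threshold (>= 10); the AUC
    score is the continuous regression output."""
    true_phq = np.asarray(true_phq, dtype=float)
    true_gad = np.asarray(true_gad, dtype=float)

    def one(pred, cls_probs, true) -> TaskMetrics:
        reg = regression_metrics(pred, true)
        t_pos = true >= SCREEN_THRESHOLD
        cm = ConfusionMatrix2.from_predictions(np.asarray(pred) >= SCREEN_THRESHOLD, t_pos)
        b = binary_metrics(cm)
        sev_pred = np.argmax(np.asarray(cls_probs), axis=1)
        sev_true = [_SEV_INDEX["severe"] if s >= 10 else (_SEV_INDEX["moderate"] if s >= 5 else 0) for s in true]
        m3, per = multiclass_confusion(sev_pred, sev_true)
        return TaskMetrics(
            mse=reg.mse, rmse=reg.rmse, mae=reg.mae, pearson_r=reg.pearson_r, r2=reg.r2,
            auc=auc(pred, t_pos),
            accuracy=b.accuracy, precision=b.precision, recall=b.recall,
            specificity=b.specificity, f1_positive=b.f1_positive, f1_macro=b.f1_macro,
            confusion2=cm, severity_confusion=m3, severity_metrics=per,
        )

    return MetricsReport(
        phq9=one(pred_phq, cls_phq, true_phq),
        gad7=one(pred_gad, cls_gad, true_gad),
        n=len(true_phq),
    )


def evaluate_records(results, records, use_ema: bool = False) -> MetricsReport:
    """Evaluate a fitted model (MultitaskResults) on labeled records."""
    out = results.predict_records(records, use_ema=use_ema)
    return metrics_from_predictions(
        out.y_phq_reg, out.y_gad_reg, out.y_phq_cls, out.y_gad_cls,
        [r.phq9 for r in records], [r.gad7 for r in records],
    )


# ---------------------------------------------------------------------------
# ablation harness
# ---------------------------------------------------------------------------

_KNOWN_COMPONENTS = ("extra_attention",)


def run_ablation(
    corpus,
    toggles,
    train_config,
    n_seeds: int = 5,
    use_augmentation: bool = False,
    vae_config=None,
    encoder_kwargs: dict | None = None,
):
    """Train the full model and the requested ablated variants under
    identical data and seeds; report per-task deltas versus the full model.

    ``toggles`` is a set of strings: ``"multitask"`` (replace the joint
    model by two single-task models), ``"augmentation"`` (train on the raw
    instead of the VAE-augmented training set) and ``"component:<name>"``
    for architectural switches (currently ``extra_attention``). The full
    model is always the reference row with deltas exactly zero.

    Returns a pandas DataFrame with mean +/- sd of dF1 (binary screening,
    per task) and dMSE over the seeds.
    """
    import pandas as pd

    from .corpus import stratified_split
    from .model import EncoderSpec, MultitaskTextModel
    from .corpus import WhitespaceTokenizer

    toggles = set(toggles)
    for t in toggles:
        if t in ("multitask", "augmentation"):
            continue
        if t.startswith("component:") and t.split(":", 1)[1] in _KNOWN_COMPONENTS:
            continue
        raise ValueError(f"unknown toggle {t!r}")
    if "augmentation" in toggles and not use_augmentation:
        log.warning("'augmentation' toggled but the full model does not augment; delta will be 0")

    encoder_kwargs = dict(encoder_kwargs or {})

    def build_model(split, extra_attention=True, augment=use_augmentation, seed=0):
        from .corpus import SplitDataset
        from .losses import LossWeights, compute_class_weights

        train_part = split.train
        # class weights always reflect the raw (pre-augmentation) training
        # distribution: synthetic oversampling already equalises exposure,
        # so recomputing weights on the augmented set would strip the
        # minority emphasis the original data calls for
        weights = LossWeights(
            class_weights_phq=compute_class_weights([r.phq9_severity for r in split.train]),
            class_weights_gad=compute_class_weights([r.gad7_severity for r in split.train]),
        )
        if augment:
            from .vae import VAEConfig, augment_to_balance

            cfg = vae_config or VAEConfig(seed=seed)
            train_part, _ = augment_to_balance(split.train, config=cfg)
        aug_split = SplitDataset(train=train_part, validation=split.validation, test=split.test, seed=split.seed)
        tok = WhitespaceTokenizer.fit(r.text for r in train_part)
        kw = dict(encoder_kwargs)
        kw.setdefault("max_len", 96)
        kw["extra_attention_blocks"] = 1 if extra_attention else 0
        spec = EncoderSpec.tiny(vocab_size=tok.vocab_size, **kw)
        return MultitaskTextModel(aug_split, tokenizer=tok, encoder_spec=spec, loss_weights=weights)

    def test_scores(res, split):
        rep = res.evaluate(split.test)
        return rep

    records = []
    per_seed: dict[str, list[dict]] = {}
    variants = ["full"] + sorted(toggles)
    for s in range(n_seeds):
        seed = train_config.seed + s
        split = stratified_split(corpus, seed=seed)
        cfgs = train_config.replace(seed=seed)

        full_model = build_model(split, seed=seed)
        full_res = full_model.fit(cfgs)
        full_rep = test_scores(full_res, split)
        base = {
            "f1_phq": full_rep.phq9.f1_positive,
            "f1_gad": full_rep.gad7.f1_positive,
            "mse_phq": full_rep.phq9.mse,
            "mse_gad": full_rep.gad7.mse,
        }
        per_seed.setdefault("full", []).append({k: 0.0 for k in base})

        for t in sorted(toggles):
            if t == "multitask":
                m = build_model(split, seed=seed)
                res_p = m.fit(cfgs, tasks="phq9")
                res_g = m.fit(cfgs, tasks="gad7")
                rep_p, rep_g = test_scores(res_p, split), test_scores(res_g, split)
                row = {
                    "f1_phq": rep_p.phq9.f1_positive - base["f1_phq"],
                    "f1_gad": rep_g.gad7.f1_positive - base["f1_gad"],
                    "mse_phq": rep_p.phq9.mse - base["mse_phq"],
                    "mse_gad": rep_g.gad7.mse - base["mse_gad"],
                }
            elif t == "augmentation":
                m = build_model(split, augment=False, seed=seed)
                rep = test_scores(m.fit(cfgs), split)
                row = {
                    "f1_phq": rep.phq9.f1_positive - base["f1_phq"],
                    "f1_gad": rep.gad7.f1_positive - base["f1_gad"],
                    "mse_phq": rep.phq9.mse - base["mse_phq"],
                    "mse_gad": rep.gad7.mse - base["mse_gad"],
                }
            else:  # component:<name>
                name = t.split(":", 1)[1]
                m = build_model(split, extra_attention=(name != "extra_attention"), seed=seed)
                rep = test_scores(m.fit(cfgs), split)
                row = {
                    "f1_phq": rep.phq9.f1_positive - base["f1_phq"],
                    "f1_gad": rep.gad7.f1_positive - base["f1_gad"],
                    "mse_phq": rep.phq9.mse - base["mse_phq"],
                    "mse_gad": rep.gad7.mse - base["mse_gad"],
                }
            per_seed.setdefault(t, []).append(row)

    for variant in variants:
        rows = per_seed[variant]
        rec = {"configuration": variant, "n_seeds": n_seeds}
        for k in ("f1_phq", "f1_gad", "mse_phq", "mse_gad"):
            vals = np.array([r[k] for r in rows])
            rec[f"delta_{k}_mean"] = vals.mean()
            rec[f"delta_{k}_sd"] = vals.std(ddof=0)
        records.append(rec)
    return pd.DataFrame(records)
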