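"""Training loop, cross-validation protocol and agreement metrics.

Separate classifiers are trained for rest and stress maps.  Evaluation
follows the clinical convention: "abnormal" is the positive class, and
agreement / sensitivity / specificity are reported in percent against the
reference labels.  Cohen's kappa is provided as a chance-corrected
agreement utility.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold

from . import nn
from .graph import polar_hierarchy
from .models import ModelConfig, TrainConfig, build_model


class TrainingError(ValueError):
    pass


@dataclass
class EvalReport:
    """Binary confusion counts with percent metrics (abnormal = positive)."""

    tp: int
    tn: int
    fp: int
    fn: int
    kappa: float | None = None

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def agreement(self) -> float:
        return 100.0 * (self.tp + self.tn) / self.n

    @property
    def sensitivity(self) -> float:
        pos = self.tp + self.fn
        return 100.0 * self.tp / pos if pos else float("nan")

    @property
    def specificity(self) -> float:
        neg = self.tn + self.fp
        return 100.0 * self.tn / neg if neg else float("nan")

    def to_dict(self) -> dict:
        return {
            "tp": self.tp,
            "tn": self.tn,
            "fp": self.fp,
            "fn": self.fn,
            "agreement": self.agreement,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "kappa": self.kappa,
        }


def evaluate(preds: np.ndarray, labels: np.ndarray, with_kappa: bool = False) -> EvalReport:
    preds = np.asarray(preds, dtype=int)
    labels = np.asarray(labels, dtype=int)
    if preds.shape != labels.shape or preds.size == 0:
        raise ValueError("need equal-length, nonempty prediction/label vectors")
    tp = int(np.sum((preds == 1) & (labels == 1)))
    tn = int(np.sum((preds == 0) & (labels == 0)))
    fp = int(np.sum((preds == 1) & (labels == 0)))
    fn = int(np.sum((preds == 0) & (labels == 1)))
    kappa = None
    if with_kappa:
        try:
            kappa = cohen_kappa(preds, labels)
        except UndefinedKappaError:
            kappa = None
    return EvalReport(tp=tp, tn=tn, fp=fp, fn=fn, kappa=kappa)


class UndefinedKappaError(ValueError):
    """Chance agreement is 1, so kappa has a zero denominator."""


def cohen_kappa(labels_a: np.ndarray, labels_b: np.ndarray) -> float:
    """Chance-corrected agreement (p_o - p_e) / (1 - p_e) for two raters."""
    a = np.asarray(labels_a, dtype=int)
    b = np.asarray(labels_b, dtype=int)
    if a.shape != b.shape or a.size == 0:
        raise ValueError("need equal-length, nonempty label vectors")
    n = a.size
    p_o = np.mean(a == b)
    classes = np.union1d(a, b)
    p_e = sum((np.mean(a == c)) * (np.mean(b == c)) for c in classes)
    if abs(1.0 - p_e) < 1e-12:
        raise UndefinedKappaError("expected agreement is 1; kappa undefined")
    return float((p_o - p_e) / (1.0 - p_e))


def train(
    model: nn.Model,
    X: np.ndarray,
    y: np.ndarray,
    cfg: TrainConfig,
) -> list[float]:
    """Seeded mini-batch SGD; returns the per-epoch mean training loss."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(X) == 0:
        raise TrainingError("empty training set")
    if np.unique(y).size < 2:
        raise TrainingError("training set must contain both classes")
    rng = np.random.default_rng(cfg.seed)
    trace: list[float] = []
    n = len(X)
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            loss = model.loss_and_grad(X[idx], y[idx])
            model.sgd_step(cfg.learning_rate)
            losses.append(loss)
        trace.append(float(np.mean(losses)))
    return trace


def crossval_4fold(
    X: np.ndarray,
    y: np.ndarray,
    model_cfg: ModelConfig,
    train_cfg: TrainConfig,
    seed: int = 0,
    n_folds: int = 4,
    with_kappa: bool = False,
) -> tuple[list[EvalReport], EvalReport]:
    """Label-stratified k-fold cross-validation of one architecture.

    Each fold is scored by a freshly initialised model trained on the other
    folds; the pooled report aggregates the per-fold confusion counts, so
    its agreement is the sample-weighted mean of the fold agreements.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(X) < 2 * n_folds:
        raise TrainingError(f"need at least {2 * n_folds} samples for {n_folds} folds")
    hierarchy = (
        polar_hierarchy(n_levels=3, seed=model_cfg.coarsen_seed)
        if model_cfg.kind.startswith("gcnn")
        else None
    )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    reports: list[EvalReport] = []
    for fold, (train_idx, test_idx) in enumerate(skf.split(X, y)):
        mcfg = ModelConfig(**{**model_cfg.to_dict(), "seed": model_cfg.seed + fold})
        tcfg = TrainConfig(**{**train_cfg.to_dict(), "seed": train_cfg.seed + fold})
        model = build_model(mcfg, hierarchy)
        train(model, X[train_idx], y[train_idx], tcfg)
        preds = model.predict(X[test_idx])
        reports.append(evaluate(preds, y[test_idx], with_kappa=with_kappa))
    pooled = EvalReport(
        tp=sum(r.tp for r in reports),
        tn=sum(r.tn for r in reports),
        fp=sum(r.fp for r in reports),
        fn=sum(r.fn for r in reports),
    )
    return reports, pooled


# ---------------------------------------------------------------------------
# Checkpoints: one .npz holding parameter tensors + JSON-encoded configs
# ---------------------------------------------------------------------------


def save_checkpoint(path, model: nn.Model, model_cfg: ModelConfig, train_cfg: TrainConfig | None = None) -> None:
    meta = {
        "model_config": model_cfg.to_dict(),
        "train_config": train_cfg.to_dict() if train_cfg else None,
    }
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **model.state_dict())


def load_checkpoint(path) -> tuple[nn.Model, ModelConfig, TrainConfig | None]:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        state = {k: data[k] for k in data.files if k != "__meta__"}
    mc = meta["model_config"]
    for key in ("cnn_filters", "cnn_kernels", "gcnn_widths", "cheb_orders", "cayley_orders", "pool_sizes"):
        mc[key] = tuple(mc[key])
    model_cfg = ModelConfig(**mc)
    train_cfg = TrainConfig(**meta["train_config"]) if meta["train_config"] else None
    model = build_model(model_cfg)
    model.load_state_dict(state)
    return model, model_cfg, train_cfg
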