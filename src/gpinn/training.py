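"""Stratified k-fold cross-validation, per-fold training and metrics.

Each of the k folds serves as the test set in turn; the next fold
(cyclically) is reserved for validation (learning-rate scheduling,
early-state restoration and probability calibration), and the remaining
folds train the model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .network import DualBranchModel, ModelConfig

log = logging.getLogger(__name__)


@dataclass
class FoldSplit:
    k: int
    seed: int
    folds: list[dict]  # per fold: {"train": [...], "val": [...], "test": [...]}

    def to_frame(self, sample_ids: list[str]) -> pd.DataFrame:
        rows = []
        for i, f in enumerate(self.folds):
            for role in ("train", "val", "test"):
                for idx in f[role]:
                    rows.append((i, sample_ids[idx], role))
        return pd.DataFrame(rows, columns=["fold", "sample", "role"])


@dataclass
class MetricsReport:
    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    precision: float
    recall: float
    f1: float
    auc_roc: float | None
    auc_pr: float | None

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def stratified_kfold(labels: np.ndarray, k: int = 20, seed: int = 0) -> FoldSplit:
    """Stratified test partition with a cyclic validation-fold assignment."""
    y = np.asarray(labels, dtype=int)
    n = len(y)
    if k < 2 or n < k:
        raise ValueError(f"need 2 <= k <= n, got k={k}, n={n}")
    counts = np.bincount(y, minlength=2)
    if counts.min() < k:
        raise ValueError(
            f"smallest class has {counts.min()} members, fewer than k={k} folds"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    test_sets = [test for _, test in skf.split(np.zeros(n), y)]
    folds = []
    for i in range(k):
        test = test_sets[i]
        val = test_sets[(i + 1) % k]
        mask = np.ones(n, dtype=bool)
        mask[test] = False
        mask[val] = False
        train = np.flatnonzero(mask)
        if train.size == 0:
            # k = 2: the cyclic validation fold would swallow the training
            # data, so validation reuses the training fold
            train = val
        folds.append({
            "train": train.tolist(),
            "val": sorted(val.tolist()),
            "test": sorted(test.tolist()),
        })
    return FoldSplit(k=k, seed=seed, folds=folds)


def evaluate(y_true, y_prob, threshold: float = 0.5) -> MetricsReport:
    """Confusion-matrix metrics at ``threshold`` (strictly greater = positive)
    plus threshold-free ROC and precision-recall areas."""
    y_true = np.asarray(y_true, dtype=int)
    y_prob = np.asarray(y_prob, dtype=float)
    if y_true.shape != y_prob.shape:
        raise ValueError("y_true and y_prob must have equal length")
    if ((y_prob < 0) | (y_prob > 1)).any():
        raise ValueError("probabilities must lie in [0, 1]")
    y_pred = (y_prob > threshold).astype(int)
    tp = int(((y_pred == 1) & (y_true == 1)).sum())
    fp = int(((y_pred == 1) & (y_true == 0)).sum())
    tn = int(((y_pred == 0) & (y_true == 0)).sum())
    fn = int(((y_pred == 0) & (y_true == 1)).sum())
    n = tp + fp + tn + fn
    accuracy = (tp + tn) / n if n else 0.0
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    if len(np.unique(y_true)) < 2:
        auc_roc = auc_pr = None
    else:
        auc_roc = float(roc_auc_score(y_true, y_prob))
        auc_pr = float(average_precision_score(y_true, y_prob))
    return MetricsReport(tp, fp, tn, fn, accuracy, precision, recall, f1, auc_roc, auc_pr)


@dataclass
class TrainHistory:
    epochs: list[int] = field(default_factory=list)
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)
    per_head: list[dict] = field(default_factory=list)
    best_epoch: int = -1

    def to_frame(self) -> pd.DataFrame:
        base = pd.DataFrame({
            "epoch": self.epochs, "train_loss": self.train_loss,
            "val_loss": self.val_loss, "lr": self.lr,
        })
        heads = pd.DataFrame([
            {f"loss_{br}_L{l}": v for (br, l), v in d.items()} for d in self.per_head
        ])
        return pd.concat([base, heads], axis=1)


def train_fold(
    model: DualBranchModel,
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_val: np.ndarray,
    y_val: np.ndarray,
    *,
    plateau_patience: int = 10,
    lr_floor: float = 1e-5,
) -> TrainHistory:
    """Train one fold with Adam, halving the learning rate on a validation-loss
    plateau and restoring the best-validation-epoch weights at the end."""
    cfg = model.config
    n = len(y_train)
    rng = np.random.default_rng(cfg.seed + 17)
    sw = None
    if cfg.class_weight == "balanced":
        counts = np.bincount(np.asarray(y_train, dtype=int), minlength=2)
        w = n / (2.0 * np.maximum(counts, 1))
        sw = w[np.asarray(y_train, dtype=int)]

    history = TrainHistory()
    lr = cfg.learning_rate
    best_val = np.inf
    best_weights = model.get_weights()
    since_improve = 0
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        ep_loss, n_batches = 0.0, 0
        ep_heads: dict = {}
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            loss, grads, per_head = model.loss_and_grads(
                x_train[idx], y_train[idx],
                sample_weight=None if sw is None else sw[idx],
            )
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}: {loss}"
                )
            model.adam_step(grads, lr=lr)
            ep_loss += loss
            n_batches += 1
            for k, v in per_head.items():
                ep_heads[k] = ep_heads.get(k, 0.0) + v
        ep_loss /= n_batches
        ep_heads = {k: v / n_batches for k, v in ep_heads.items()}

        val_loss, _, _ = model.loss_and_grads(x_val, y_val, training=False)
        history.epochs.append(epoch)
        history.train_loss.append(ep_loss)
        history.val_loss.append(float(val_loss))
        history.lr.append(lr)
        history.per_head.append(ep_heads)

        if val_loss < best_val - 1e-9:
            best_val = val_loss
            best_weights = model.get_weights()
            history.best_epoch = epoch
            since_improve = 0
        else:
            since_improve += 1
            if since_improve >= plateau_patience and lr > lr_floor:
                lr = max(lr / 2.0, lr_floor)
                since_improve = 0
                log.debug("epoch %d: halving learning rate to %g", epoch, lr)
    if cfg.epochs > 0:
        model.set_weights(best_weights)
    return history


@dataclass
class FoldResult:
    fold: int
    metrics: MetricsReport
    model: DualBranchModel
    history: TrainHistory
    test_idx: list[int]
    val_idx: list[int]
    train_idx: list[int]
    y_prob_test: np.ndarray
    y_prob_val: np.ndarray


def cross_validate(
    config: ModelConfig,
    masks_ontology,
    masks_pathway,
    gene_mask,
    x: np.ndarray,
    y: np.ndarray,
    k: int = 20,
    seed: int = 0,
) -> list[FoldResult]:
    """Train and evaluate one model per fold; each fold's test set is disjoint."""
    split = stratified_kfold(y, k=k, seed=seed)
    results = []
    for i, f in enumerate(split.folds):
        cfg = ModelConfig(**{**config.__dict__, "seed": config.seed + i})
        model = DualBranchModel(masks_ontology, masks_pathway, gene_mask, cfg)
        tr, va, te = f["train"], f["val"], f["test"]
        history = train_fold(model, x[tr], y[tr], x[va], y[va])
        y_prob_test = model.predict_proba(x[te])
        y_prob_val = model.predict_proba(x[va])
        metrics = evaluate(y[te], y_prob_test)
        results.append(FoldResult(i, metrics, model, history, te, va, tr,
                                  y_prob_test, y_prob_val))
        log.info("fold %d: acc=%.3f auc=%s", i, metrics.accuracy, metrics.auc_roc)
    return results


def summarize(results: list[FoldResult]) -> pd.DataFrame:
    rows = [dict(fold=r.fold, **r.metrics.to_dict()) for r in results]
    return pd.DataFrame(rows)
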