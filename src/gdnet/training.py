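"""Training loop, two-stage transfer, k-fold evaluation and metrics.

The loss is categorical cross-entropy over segment softmax outputs plus
an L2 penalty, ``-(1/n) ΣΣ y_ij log s_ij + λ|w|²`` with λ = 0.001 by
default.  Weights are initialised from a Gaussian with mean 0 and
variance 0.01 (std 0.1); biases start at zero and batch norm at
identity.  Optimisation is mini-batch Adam (lr 0.001, batch 64) with
early stopping on validation loss.

Evaluation uses stratified k-fold cross-validation (k = 10 by default)
that is additionally *grouped by source trial*: segments cut from one
trial never straddle a train/test split, which prevents trivially easy
within-trial leakage.  Accuracy, sensitivity and specificity are
computed from one-vs-rest confusion counts per class and macro-averaged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.model_selection import StratifiedGroupKFold

from . import nn
from .model import GDNet, GDNetConfig, build_model
from .preprocessing import SegmentBatch

logger = logging.getLogger("gdnet")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    learning_rate: float = 0.001
    batch_size: int = 64            # segments per mini-batch (see batch_by_trial)
    l2_lambda: float = 0.001
    init_std: float = 0.1           # Gaussian init: mean 0, variance 0.01
    early_stop_patience: int = 10
    max_epochs: int = 200
    seed: int = 0
    batch_by_trial: bool = False    # interpret batch_size as trials (t*D_b segments)

    def __post_init__(self):
        if self.learning_rate <= 0 or self.batch_size <= 0 or self.max_epochs < 0:
            raise ValueError("learning rate and batch size must be positive, "
                             "max_epochs non-negative")
        if self.l2_lambda < 0 or self.early_stop_patience < 0:
            raise ValueError("l2_lambda and patience must be non-negative")


# ---------------------------------------------------------------------------
# loss and initialisation
# ---------------------------------------------------------------------------

def loss(softmax_outputs: np.ndarray, one_hot_labels: np.ndarray,
         model_weights: Sequence[np.ndarray] = (), l2_lambda: float = 0.0,
         eps: float = 1e-12) -> float:
    """Categorical cross-entropy plus L2 penalty, as a closed form.

    ``softmax_outputs`` rows must sum to one; zero probabilities at the
    true class are clamped at ``eps`` (and logged) rather than producing
    infinities.
    """
    s = np.asarray(softmax_outputs, dtype=np.float64)
    y = np.asarray(one_hot_labels, dtype=np.float64)
    if s.shape != y.shape:
        raise ValueError(f"prediction shape {s.shape} != label shape {y.shape}")
    picked = (s * y).sum(axis=1)
    if np.any(picked <= 0):
        logger.warning("zero predicted probability at a true class; clamping at %g", eps)
        picked = np.clip(picked, eps, None)
    ce = float(-np.log(picked).mean())
    l2 = l2_lambda * float(sum(np.sum(np.square(np.asarray(w, dtype=np.float64)))
                               for w in model_weights))
    return ce + l2


def init_weights(model: GDNet, seed: int) -> GDNet:
    """Draw every convolution/dense/attention weight i.i.d. from
    N(0, 0.01); zero all biases; batch norm stays at identity."""
    rng = np.random.default_rng(seed)
    for p in model.network.parameters().values():
        if p.decay:  # weight matrices
            p.value = rng.normal(0.0, 0.1, size=p.value.shape).astype(p.value.dtype)
        elif "bias" in p.name or "shift" in p.name:
            p.value = np.zeros_like(p.value)
        # batch-norm scale stays at its identity initialisation
        p.grad = np.zeros_like(p.value)
    return model


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _evaluate_loss_acc(model: GDNet, batch: SegmentBatch, lam: float,
                       chunk: int = 256) -> tuple[float, float]:
    params = model.network.parameters().values()
    losses, hits = [], 0
    for start in range(0, len(batch), chunk):
        X = batch.X[start:start + chunk]
        y = batch.y[start:start + chunk]
        logits = model.logits(X, training=False)
        ce, _ = nn.softmax_cross_entropy(logits, y)
        losses.append(ce * len(y))
        hits += int((logits.argmax(axis=1) == y).sum())
    ce = sum(losses) / len(batch)
    return ce + nn.l2_penalty(params, lam), hits / len(batch)


def train(model: GDNet, train_segments: SegmentBatch, val_segments: SegmentBatch,
          cfg: TrainConfig) -> dict:
    """Mini-batch Adam training with early stopping on validation loss.

    Returns the history dict (per-epoch train/val loss and accuracy);
    the model is left holding the best-validation-loss weights.
    """
    if len(train_segments) == 0 or len(val_segments) == 0:
        raise ValueError("training and validation sets must be non-empty")
    rng = np.random.default_rng(cfg.seed)
    model.network.set_rng(rng)
    params = model.network.parameters()
    opt = nn.Adam(params, lr=cfg.learning_rate)
    lam = cfg.l2_lambda

    if cfg.batch_by_trial:
        # batch_size counts trials: gather all segments of D_b trials per step
        trial_ids = train_segments.source_trial_ids
        unique_trials = np.unique(trial_ids)
        seg_of_trial = {t: np.flatnonzero(trial_ids == t) for t in unique_trials}

    history = {"train_loss": [], "train_acc": [], "val_loss": [], "val_acc": []}
    best_val = np.inf
    best_state = model.network.state_dict()
    bad_epochs = 0
    n = len(train_segments)

    for epoch in range(cfg.max_epochs):
        if cfg.batch_by_trial:
            order_t = rng.permutation(unique_trials)
            batches = [np.concatenate([seg_of_trial[t] for t in order_t[s:s + cfg.batch_size]])
                       for s in range(0, len(order_t), cfg.batch_size)]
        else:
            order = rng.permutation(n)
            batches = [order[s:s + cfg.batch_size] for s in range(0, n, cfg.batch_size)]
        ep_loss, ep_hits = 0.0, 0
        for idx in batches:
            X, y = train_segments.X[idx], train_segments.y[idx]
            model.network.zero_grad()
            logits = model.logits(X, training=True)
            ce, dlogits = nn.softmax_cross_entropy(logits, y)
            model.network.backward(dlogits)
            nn.add_l2_gradients(params.values(), lam)
            opt.step()
            ep_loss += ce * len(y)
            ep_hits += int((logits.argmax(axis=1) == y).sum())
        train_loss = ep_loss / n + nn.l2_penalty(params.values(), lam)
        val_loss, val_acc = _evaluate_loss_acc(model, val_segments, lam)
        history["train_loss"].append(train_loss)
        history["train_acc"].append(ep_hits / n)
        history["val_loss"].append(val_loss)
        history["val_acc"].append(val_acc)

        if val_loss < best_val - 1e-9:
            best_val = val_loss
            best_state = model.network.state_dict()
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs > cfg.early_stop_patience:
                logger.info("early stop at epoch %d (best val loss %.4f)",
                            epoch + 1, best_val)
                break
    model.network.load_state_dict(best_state)
    return history


def two_stage_train(model: GDNet, stage1_train: SegmentBatch, stage1_val: SegmentBatch,
                    stage2_train: SegmentBatch, stage2_val: SegmentBatch,
                    cfg: TrainConfig, stage2_cfg: TrainConfig | None = None,
                    checkpoint_dir=None) -> tuple[GDNet, dict]:
    """Pre-train on one dataset, then fine-tune on a second.

    Stage 1 starts from the Gaussian initialisation; stage 2 re-initialises
    the network with the stage-1 weights and fine-tunes.  Both stage
    checkpoints are persisted when ``checkpoint_dir`` is given.  A stage-2
    config with ``max_epochs=0`` returns the stage-1 weights unchanged.
    """
    for a, b in ((stage1_train, stage2_train),):
        if a.n_channels != b.n_channels:
            raise ValueError("stage datasets must share the channel count")
    init_weights(model, cfg.seed)
    hist1 = train(model, stage1_train, stage1_val, cfg)
    if checkpoint_dir is not None:
        from pathlib import Path
        model.save(Path(checkpoint_dir) / "stage1.npz")
    s2 = stage2_cfg if stage2_cfg is not None else cfg
    hist2: dict = {}
    if s2.max_epochs > 0:
        hist2 = train(model, stage2_train, stage2_val, s2)
    if checkpoint_dir is not None:
        from pathlib import Path
        model.save(Path(checkpoint_dir) / "stage2.npz")
    return model, {"stage1": hist1, "stage2": hist2}


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionCounts:
    """One-vs-rest confusion counts for a single class."""
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion_counts(y_true: np.ndarray, y_pred: np.ndarray,
                     n_classes: int) -> list[ConfusionCounts]:
    """Per-class one-vs-rest counts; TP+TN+FP+FN equals the prediction
    total for every class."""
    from sklearn.metrics import confusion_matrix
    cm = confusion_matrix(y_true, y_pred, labels=np.arange(n_classes))
    total = cm.sum()
    out = []
    for k in range(n_classes):
        tp = int(cm[k, k])
        fn = int(cm[k].sum() - tp)
        fp = int(cm[:, k].sum() - tp)
        tn = int(total - tp - fn - fp)
        out.append(ConfusionCounts(tp, tn, fp, fn))
    return out


def metrics_from_confusion(counts: ConfusionCounts) -> tuple[float, float, float]:
    """ACC = (TP+TN)/total, SEN = TP/(TP+FN), SPE = TN/(TN+FP).

    A zero denominator yields 0.0 for that metric and a log warning.
    """
    c = counts
    if min(c.tp, c.tn, c.fp, c.fn) < 0:
        raise ValueError("confusion counts must be non-negative")
    acc = (c.tp + c.tn) / c.total if c.total else 0.0
    if c.tp + c.fn == 0:
        logger.warning("SEN undefined (TP+FN = 0); reporting 0")
        sen = 0.0
    else:
        sen = c.tp / (c.tp + c.fn)
    if c.tn + c.fp == 0:
        logger.warning("SPE undefined (TN+FP = 0); reporting 0")
        spe = 0.0
    else:
        spe = c.tn / (c.tn + c.fp)
    return acc, sen, spe


def macro_metrics(y_true: np.ndarray, y_pred: np.ndarray,
                  n_classes: int) -> tuple[float, float, float]:
    """Macro-averaged one-vs-rest ACC/SEN/SPE as fractions in [0, 1]."""
    per_class = [metrics_from_confusion(c)
                 for c in confusion_counts(y_true, y_pred, n_classes)]
    arr = np.array(per_class)
    return tuple(arr.mean(axis=0))


@dataclass
class MetricsReport:
    """Per-fold ACC/SEN/SPE percentages with their mean and STD."""

    fold_acc: list[float]
    fold_sen: list[float]
    fold_spe: list[float]

    @property
    def acc(self) -> tuple[float, float]:
        return float(np.mean(self.fold_acc)), float(np.std(self.fold_acc))

    @property
    def sen(self) -> tuple[float, float]:
        return float(np.mean(self.fold_sen)), float(np.std(self.fold_sen))

    @property
    def spe(self) -> tuple[float, float]:
        return float(np.mean(self.fold_spe)), float(np.std(self.fold_spe))

    def to_dataframe(self):
        import pandas as pd
        return pd.DataFrame({
            "fold": np.arange(len(self.fold_acc)),
            "acc": self.fold_acc, "sen": self.fold_sen, "spe": self.fold_spe,
        })


# ---------------------------------------------------------------------------
# classifier wrapper and k-fold evaluation
# ---------------------------------------------------------------------------

class GDNetClassifier:
    """fit/predict wrapper used by the cross-validation harness.

    ``fit`` carves a validation split (grouped by trial) out of the
    training segments for early stopping, initialises the weights and
    trains.
    """

    def __init__(self, model_cfg: GDNetConfig, train_cfg: TrainConfig,
                 val_fraction: float = 0.15):
        self.model_cfg = model_cfg
        self.train_cfg = train_cfg
        self.val_fraction = val_fraction
        self.model: GDNet | None = None
        self.history: dict | None = None

    def fit(self, segments: SegmentBatch) -> "GDNetClassifier":
        rng = np.random.default_rng(self.train_cfg.seed)
        trials = np.unique(segments.source_trial_ids)
        n_val = max(1, int(round(self.val_fraction * len(trials))))
        val_trials = rng.choice(trials, size=n_val, replace=False)
        val_mask = np.isin(segments.source_trial_ids, val_trials)
        train_b, val_b = segments.subset(~val_mask), segments.subset(val_mask)
        self.model = init_weights(build_model(self.model_cfg), self.train_cfg.seed)
        self.history = train(self.model, train_b, val_b, self.train_cfg)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        if self.model is None:
            raise RuntimeError("fit before predict")
        preds = []
        for start in range(0, len(X), 256):
            preds.append(self.model.predict(X[start:start + 256]))
        return np.concatenate(preds)


def kfold_evaluate(segments: SegmentBatch, classifier_builder: Callable[[], object],
                   k: int = 10, seed: int = 0) -> MetricsReport:
    """Stratified, trial-grouped k-fold cross-validation.

    ``classifier_builder`` returns a fresh object with ``fit(SegmentBatch)``
    and ``predict(X)``.  Raises if a class is absent from any training
    split (stratification failure).
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(segments) < k:
        raise ValueError(f"dataset of {len(segments)} segments cannot be split "
                         f"into {k} folds")
    n_classes = int(segments.y.max()) + 1
    splitter = StratifiedGroupKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_acc, fold_sen, fold_spe = [], [], []
    for fold, (tr_idx, te_idx) in enumerate(
            splitter.split(segments.X, segments.y, groups=segments.source_trial_ids)):
        tr, te = segments.subset(tr_idx), segments.subset(te_idx)
        if len(np.unique(tr.y)) < n_classes:
            raise ValueError(f"fold {fold}: a class is missing from the training split")
        clf = classifier_builder()
        clf.fit(tr)
        y_pred = clf.predict(te.X)
        acc, sen, spe = macro_metrics(te.y, y_pred, n_classes)
        fold_acc.append(100.0 * acc)
        fold_sen.append(100.0 * sen)
        fold_spe.append(100.0 * spe)
        logger.info("fold %d: ACC %.2f%% SEN %.2f%% SPE %.2f%%",
                    fold, fold_acc[-1], fold_sen[-1], fold_spe[-1])
    return MetricsReport(fold_acc, fold_sen, fold_spe)
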