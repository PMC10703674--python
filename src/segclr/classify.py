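"""Classifiers over embeddings and the evaluation protocols around them.

Two model families operate on (aggregated) embedding vectors: a
multinomial linear probe and a shallow two-module residual MLP
("ResNet-2"). A fully supervised 3D convolutional baseline trains the
same trunk as the contrastive encoder directly on voxel views with a
softmax head, for label-efficiency comparisons.

The evaluation protocols mirror common practice for fragment-level cell
typing: label-efficiency subsampling with per-class floors, class
rebalancing by upsampling to the most numerous class, 75/25 cell-level
cross-validation repeated 10 times with equal-class example sampling,
and class collapsing by probability summation.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from .nn import (Adam, Dense, ReLU, Sequential, build_trunk, EncoderConfig,
                 softmax_cross_entropy, parameter_count)
from .nn.layers import Layer
from .views import augment


@dataclass
class ClassifierOutput:
    class_names: list[str]
    probabilities: np.ndarray  # (n, K), rows sum to 1

    def __post_init__(self):
        p = self.probabilities
        if np.any(p < -1e-9) or np.any(np.abs(p.sum(axis=1) - 1) > 1e-6):
            raise ValueError("probabilities must be non-negative and normalized")

    @property
    def predicted(self) -> np.ndarray:
        idx = self.probabilities.argmax(axis=1)
        return np.asarray(self.class_names, dtype=object)[idx]


# ---------------------------------------------------------------------------
# linear probe


class LinearProbe:
    """Multinomial logistic regression on embedding vectors."""

    def __init__(self, model: LogisticRegression):
        self.model = model

    @property
    def class_names(self) -> list[str]:
        return [str(c) for c in self.model.classes_]

    def predict_output(self, x: np.ndarray) -> ClassifierOutput:
        return ClassifierOutput(self.class_names, self.model.predict_proba(x))

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.model.predict(x)


def train_linear(embeddings: np.ndarray, labels, seed: int = 0,
                 c: float = 1.0, max_iter: int = 2000) -> LinearProbe:
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    if counts.min() < 3:
        raise ValueError("need at least 3 examples per class")
    model = LogisticRegression(C=c, max_iter=max_iter, random_state=seed)
    model.fit(embeddings, labels)
    return LinearProbe(model)


# ---------------------------------------------------------------------------
# shallow residual MLP ("ResNet-2")


class _ResidualBlock(Layer):
    def __init__(self, width: int, rng):
        self.fc1 = Dense(width, width, rng=rng)
        self.relu1 = ReLU()
        self.fc2 = Dense(width, width, rng=rng)
        self.relu_out = ReLU()

    def parameters(self):
        out = []
        for pname, lay in (("fc1", self.fc1), ("fc2", self.fc2)):
            for name, v, g in lay.parameters():
                out.append((f"{pname}.{name}", v, g))
        return out

    def forward(self, x):
        h = self.fc2.forward(self.relu1.forward(self.fc1.forward(x)))
        return self.relu_out.forward(h + x)

    def backward(self, grad):
        g = self.relu_out.backward(grad)
        gh = self.fc1.backward(self.relu1.backward(self.fc2.backward(g)))
        return gh + g

    def set_training(self, flag):
        pass


class ResNet2:
    """Two fully connected residual modules with a softmax output."""

    def __init__(self, in_dim: int, class_names: list[str], width: int = 128,
                 seed: int = 0):
        rng = np.random.default_rng(seed)
        self.class_names = list(class_names)
        self.width = width
        self.stem = Dense(in_dim, width, rng=rng)
        self.block1 = _ResidualBlock(width, rng)
        self.block2 = _ResidualBlock(width, rng)
        self.head = Dense(width, len(class_names), rng=rng)
        self.net = Sequential(self.stem, ReLU(), self.block1, self.block2,
                              self.head)
        # standardization fitted on training data
        self.mu = np.zeros(in_dim, dtype=np.float32)
        self.sd = np.ones(in_dim, dtype=np.float32)

    def hidden(self, x: np.ndarray) -> np.ndarray:
        """Penultimate representation (input to the output layer)."""
        h = (np.asarray(x, np.float32) - self.mu) / self.sd
        for lay in self.net.layers[:-1]:
            h = lay.forward(h)
        return h

    def logits(self, x: np.ndarray) -> np.ndarray:
        return self.net.forward((np.asarray(x, np.float32) - self.mu) / self.sd)

    def predict_output(self, x: np.ndarray) -> ClassifierOutput:
        z = self.logits(x)
        z = z - z.max(axis=1, keepdims=True)
        p = np.exp(z)
        p /= p.sum(axis=1, keepdims=True)
        return ClassifierOutput(self.class_names, p)

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.predict_output(x).predicted


def train_resnet2(embeddings: np.ndarray, labels, seed: int = 0,
                  width: int = 128, epochs: int = 60, batch_size: int = 64,
                  lr: float = 1e-3) -> ResNet2:
    """Train the shallow residual classifier with Adam; deterministic."""
    x = np.asarray(embeddings, dtype=np.float32)
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    if counts.min() < 3:
        raise ValueError("need at least 3 examples per class")
    names = [str(c) for c in classes]
    y = np.searchsorted(classes, labels)
    model = ResNet2(x.shape[1], names, width=width, seed=seed)
    model.mu = x.mean(axis=0).astype(np.float32)
    model.sd = (x.std(axis=0) + 1e-6).astype(np.float32)
    xs = (x - model.mu) / model.sd
    rng = np.random.default_rng(seed + 1)
    opt = Adam(model.net.parameters(), lr=lr)
    n = len(xs)
    for _ in range(epochs):
        order = rng.permutation(n)
        for i in range(0, n, batch_size):
            idx = order[i:i + batch_size]
            logits = model.net.forward(xs[idx])
            _, dlogits = softmax_cross_entropy(logits, y[idx])
            model.net.backward(dlogits)
            opt.step()
    return model


# ---------------------------------------------------------------------------
# supervised voxel baseline


class SupervisedBaseline:
    """Contrastive-encoder trunk + classification softmax, trained on views."""

    def __init__(self, config: EncoderConfig, class_names: list[str],
                 seed: int = 0):
        rng = np.random.default_rng(seed)
        self.config = config
        self.class_names = list(class_names)
        self.trunk = build_trunk(config, rng=rng)
        self.head = Dense(config.block_widths[-1], len(class_names), rng=rng)
        self.net = Sequential(self.trunk, self.head)

    def trunk_parameter_count(self) -> int:
        return parameter_count(self.trunk)

    def predict_output(self, views: np.ndarray, batch_size: int = 16) -> ClassifierOutput:
        self.net.set_training(False)
        out = []
        for i in range(0, len(views), batch_size):
            z = self.net.forward(views[i:i + batch_size])
            z = z - z.max(axis=1, keepdims=True)
            p = np.exp(z)
            out.append(p / p.sum(axis=1, keepdims=True))
        return ClassifierOutput(self.class_names, np.concatenate(out))

    def predict(self, views: np.ndarray) -> np.ndarray:
        return self.predict_output(views).predicted


def supervised_baseline(views: list, labels, seed: int = 0,
                        config: EncoderConfig | None = None,
                        steps: int = 150, batch_size: int = 16,
                        lr: float = 0.003, rebalance: bool = True) -> SupervisedBaseline:
    """Train a fully supervised classifier directly on masked voxel views.

    Uses the supervised augmentation mode (reflections + axis-aligned
    90-degree rotations, no photometric jitter) and class rebalancing by
    upsampling to the most numerous class.
    """
    from .views import views_to_batch

    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    names = [str(c) for c in classes]
    y = np.searchsorted(classes, labels)
    if config is None:
        config = EncoderConfig.toy(view_size=views[0].view_size)
    model = SupervisedBaseline(config, names, seed=seed)
    idx_pool = rebalance_upsample(labels) if rebalance else np.arange(len(labels))
    rng = np.random.default_rng(seed + 1)
    opt = Adam(model.net.parameters(), lr=lr)
    model.net.set_training(True)
    for step in range(steps):
        idx = idx_pool[rng.integers(0, len(idx_pool), size=batch_size)]
        batch_views = [augment(views[i], seed=int(rng.integers(1 << 31)),
                               mode="supervised") for i in idx]
        x = views_to_batch(batch_views)
        logits = model.net.forward(x)
        loss, dlogits = softmax_cross_entropy(logits, y[idx])
        if not np.isfinite(loss):
            raise RuntimeError(f"supervised training diverged at step {step}")
        model.net.backward(dlogits)
        opt.step()
    return model


# ---------------------------------------------------------------------------
# protocols


def subsample_training_set(labels, target_n: int, seed: int = 0,
                           min_per_class: int = 3, min_frac: float = 0.10,
                           max_tries: int = 1000) -> np.ndarray:
    """Uniform subsample with per-class floors.

    Resamples until every class holds at least ``min_per_class`` examples
    and at least ``min_frac`` of the drawn sample (the floor is applied
    per class); raises if the constraints are infeasible after bounded
    retries.
    """
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if target_n > len(labels):
        raise ValueError("target_n exceeds dataset size")
    if target_n < min_per_class * len(classes):
        raise ValueError("target_n too small for per-class floors")
    if target_n == len(labels):
        return np.arange(len(labels))
    floor = max(min_per_class, int(np.ceil(min_frac * target_n)))
    rng = np.random.default_rng(seed)
    for _ in range(max_tries):
        idx = rng.choice(len(labels), size=target_n, replace=False)
        _, counts = np.unique(labels[idx], return_counts=True)
        if (len(counts) == len(classes) and counts.min() >= floor):
            return np.sort(idx)
    raise ValueError(
        f"could not satisfy class floors (>= {floor} per class) in "
        f"{max_tries} draws")


def rebalance_upsample(labels) -> np.ndarray:
    """Indices upsampling every class to the most numerous class's count.

    Original indices come first in their original order; minority classes
    are then repeated cyclically from the start of their index lists.
    """
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    target = counts.max()
    extra = []
    for cls, cnt in zip(classes, counts):
        idx = np.flatnonzero(labels == cls)
        need = target - cnt
        if need > 0:
            reps = np.tile(idx, int(np.ceil(need / cnt)))[:need]
            extra.append(reps)
    if extra:
        return np.concatenate([np.arange(len(labels))] + extra)
    return np.arange(len(labels))


def collapse_classes(output: ClassifierOutput,
                     class_mapping: dict[str, str]) -> ClassifierOutput:
    """Merge classes by summing their probabilities.

    ``class_mapping`` maps every original class name to a merged name;
    merged classes keep the order of first appearance.
    """
    missing = [c for c in output.class_names if c not in class_mapping]
    if missing:
        raise ValueError(f"mapping misses classes: {missing}")
    merged_names: list[str] = []
    for c in output.class_names:
        m = class_mapping[c]
        if m not in merged_names:
            merged_names.append(m)
    p = np.zeros((len(output.probabilities), len(merged_names)))
    for j, c in enumerate(output.class_names):
        p[:, merged_names.index(class_mapping[c])] += output.probabilities[:, j]
    return ClassifierOutput(merged_names, p)


# ---------------------------------------------------------------------------
# metrics


def confusion_matrix(y_true, y_pred, class_names) -> np.ndarray:
    k = len(class_names)
    index = {c: i for i, c in enumerate(class_names)}
    cm = np.zeros((k, k), dtype=np.int64)
    for t, p in zip(y_true, y_pred):
        cm[index[t], index[p]] += 1
    return cm


def f1_from_confusion(cm: np.ndarray) -> np.ndarray:
    """Per-class F1 from a confusion matrix (rows = true, cols = predicted)."""
    tp = np.diag(cm).astype(float)
    fp = cm.sum(axis=0) - tp
    fn = cm.sum(axis=1) - tp
    denom = 2 * tp + fp + fn
    with np.errstate(invalid="ignore", divide="ignore"):
        f1 = np.where(denom > 0, 2 * tp / denom, 0.0)
    return f1


def macro_f1(y_true, y_pred, class_names=None) -> float:
    if class_names is None:
        class_names = sorted(set(map(str, y_true)) | set(map(str, y_pred)))
    cm = confusion_matrix(np.asarray(y_true, dtype=object).astype(str),
                          np.asarray(y_pred, dtype=object).astype(str),
                          list(class_names))
    return float(f1_from_confusion(cm).mean())


# ---------------------------------------------------------------------------
# cell-level cross-validation


@dataclass
class CVResult:
    class_names: list[str]
    per_run_f1: list[np.ndarray]      # per run, per class
    mean_f1: float
    pooled_confusion: np.ndarray
    run_details: list[dict] = field(default_factory=list)


def _equal_class_sample(labels: np.ndarray, n_total: int,
                        rng: np.random.Generator) -> np.ndarray:
    classes = np.unique(labels)
    per = max(1, n_total // len(classes))
    out = []
    for cls in classes:
        idx = np.flatnonzero(labels == cls)
        out.append(rng.choice(idx, size=per, replace=len(idx) < per))
    return np.concatenate(out)


def cell_level_cv(embeddings: np.ndarray, emb_cell_ids: np.ndarray,
                  cell_labels: dict[int, str], classifier_factory,
                  n_repeats: int = 10, train_frac: float = 0.75,
                  samples_per_run: int = 1000, seed: int = 0) -> CVResult:
    """Cell-level cross-validated fragment classification.

    Cells are split 75/25 per class (no cell contributes embeddings to
    both sides of a run); training embeddings are sampled equally across
    classes; test-side class imbalance is corrected by repeating minority
    examples. Per-class F1 is computed per run and averaged; confusion
    matrices are pooled over runs and then equal-class resampled.
    """
    emb_cell_ids = np.asarray(emb_cell_ids)
    cells = np.array(sorted(cell_labels))
    cell_cls = np.array([cell_labels[c] for c in cells])
    class_names = sorted(set(cell_cls))
    for cls in class_names:
        if (cell_cls == cls).sum() < 4:
            raise ValueError(f"class {cls!r} has fewer than 4 cells")
    emb_labels = np.array([cell_labels[c] for c in emb_cell_ids])
    rng = np.random.default_rng(seed)
    per_run_f1, run_details = [], []
    pooled_true, pooled_pred = [], []
    for run in range(n_repeats):
        train_cells, test_cells = set(), set()
        for cls in class_names:
            ids = cells[cell_cls == cls]
            perm = rng.permutation(len(ids))
            n_train = max(1, int(round(train_frac * len(ids))))
            n_train = min(n_train, len(ids) - 1)
            train_cells.update(ids[perm[:n_train]])
            test_cells.update(ids[perm[n_train:]])
        tr_mask = np.isin(emb_cell_ids, list(train_cells))
        te_mask = np.isin(emb_cell_ids, list(test_cells))
        tr_idx = np.flatnonzero(tr_mask)
        tr_pick = tr_idx[_equal_class_sample(emb_labels[tr_idx],
                                             samples_per_run, rng)]
        clf = classifier_factory(embeddings[tr_pick], emb_labels[tr_pick],
                                 int(rng.integers(1 << 31)))
        te_idx = np.flatnonzero(te_mask)
        te_bal = te_idx[rebalance_upsample(emb_labels[te_idx])]
        pred = np.asarray(clf.predict(embeddings[te_bal])).astype(str)
        true = emb_labels[te_bal].astype(str)
        cm = confusion_matrix(true, pred, class_names)
        per_run_f1.append(f1_from_confusion(cm))
        pooled_true.append(true)
        pooled_pred.append(pred)
        run_details.append({"run": run, "train_cells": sorted(train_cells),
                            "test_cells": sorted(test_cells)})
    mean_f1 = float(np.mean([f.mean() for f in per_run_f1]))
    # pool test sets over runs, then equal-class resample
    true_all = np.concatenate(pooled_true)
    pred_all = np.concatenate(pooled_pred)
    pick = _equal_class_sample(true_all, len(true_all), rng)
    pooled_cm = confusion_matrix(true_all[pick], pred_all[pick], class_names)
    return CVResult(class_names, per_run_f1, mean_f1, pooled_cm, run_details)
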