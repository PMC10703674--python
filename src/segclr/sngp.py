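"""Distance-aware uncertainty: spectral-normalized residual classifier
with a Gaussian-process output layer (SNGP).

The classifier is the shallow two-module residual MLP with its hidden
weights constrained to bounded spectral norm (keeping the hidden map
approximately distance preserving) and the output layer replaced by a
random-Fourier-feature approximation of a Gaussian process:

    phi(h) = sqrt(2/D) * cos(W h + b),   logits = phi(h) @ beta

with W, b fixed at initialization and beta trained by cross-entropy. A
Laplace approximation of the posterior precision over beta,

    Sigma^-1 = ridge * I + sum_i p_i (1 - p_i) phi_i phi_i^T,

yields a per-example predictive logit variance sigma^2(x) = phi^T Sigma
phi. Logits are shrunk by the mean-field rule h / sqrt(1 + lambda *
sigma^2) before the softmax, and predictive uncertainty is summarized by
the Dempster-Shafer metric u = K / (K + sum_k exp(h_k)), which grows
toward 1 as all (adjusted) logits shrink — i.e. far from training data.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .classify import ClassifierOutput, _ResidualBlock, f1_from_confusion
from .nn import Adam, Dense, ReLU, Sequential, softmax_cross_entropy

MEAN_FIELD_LAMBDA = 3.0 / math.pi ** 2


def dempster_shafer(logits: np.ndarray, k: int | None = None) -> np.ndarray:
    """u(x) = K / (K + sum_k exp(h_k(x))); rows are examples."""
    h = np.asarray(logits, dtype=float)
    if h.ndim == 1:
        h = h[None]
        squeeze = True
    else:
        squeeze = False
    if not np.isfinite(h).all():
        raise ValueError("non-finite logits")
    kk = h.shape[1] if k is None else k
    if kk < 2:
        raise ValueError("need at least 2 classes")
    u = kk / (kk + np.exp(h).sum(axis=1))
    return float(u[0]) if squeeze else u


def mean_field_adjust(logits: np.ndarray, variance: np.ndarray,
                      lam: float = MEAN_FIELD_LAMBDA) -> np.ndarray:
    """h_lambda = h / sqrt(1 + lambda * sigma^2), per example."""
    h = np.asarray(logits, dtype=float)
    var = np.asarray(variance, dtype=float)
    if np.any(var < 0) or lam < 0:
        raise ValueError("variance and lambda must be non-negative")
    scale = np.sqrt(1.0 + lam * var)
    if h.ndim == 2:
        scale = scale.reshape(-1, 1)
    return h / scale


@dataclass
class UncertaintyOutput:
    class_names: list[str]
    logits: np.ndarray          # raw GP mean logits (n, K)
    variance: np.ndarray        # sigma^2 per example (n,)
    adjusted_logits: np.ndarray
    uncertainty: np.ndarray     # Dempster-Shafer u per example (n,)
    lam: float

    @property
    def probabilities(self) -> np.ndarray:
        z = self.adjusted_logits - self.adjusted_logits.max(axis=1, keepdims=True)
        p = np.exp(z)
        return p / p.sum(axis=1, keepdims=True)

    @property
    def predicted(self) -> np.ndarray:
        idx = self.adjusted_logits.argmax(axis=1)
        return np.asarray(self.class_names, dtype=object)[idx]


class _SpectralNorm:
    """One-step power iteration; rescales W to spectral norm <= bound."""

    def __init__(self, dense: Dense, bound: float, rng):
        self.dense = dense
        self.bound = bound
        self.u = rng.standard_normal(dense.w.shape[1])
        self.u /= np.linalg.norm(self.u)

    def apply(self):
        w = self.dense.w
        v = w @ self.u
        v /= (np.linalg.norm(v) + 1e-12)
        u = w.T @ v
        sigma = float(np.linalg.norm(u))
        self.u = u / (sigma + 1e-12)
        if sigma > self.bound:
            w *= self.bound / sigma


class SNGPClassifier:
    """Spectral-normalized ResNet-2 trunk + random-feature GP output."""

    def __init__(self, in_dim: int, class_names: list[str], width: int = 128,
                 rff_dim: int = 1024, lengthscale: float = 2.0,
                 norm_bound: float = 0.95, ridge: float = 1.0,
                 lam: float = MEAN_FIELD_LAMBDA, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.class_names = list(class_names)
        self.lam = lam
        self.ridge = ridge
        self.stem = Dense(in_dim, width, rng=rng)
        self.block1 = _ResidualBlock(width, rng)
        self.block2 = _ResidualBlock(width, rng)
        self.trunk = Sequential(self.stem, ReLU(), self.block1, self.block2)
        self.sn = [_SpectralNorm(d, norm_bound, rng) for d in
                   (self.stem, self.block1.fc1, self.block1.fc2,
                    self.block2.fc1, self.block2.fc2)]
        # fixed random Fourier features
        self.rff_w = (rng.standard_normal((width, rff_dim))
                      / lengthscale).astype(np.float32)
        self.rff_b = rng.uniform(0, 2 * np.pi, size=rff_dim).astype(np.float32)
        self.beta = Dense(rff_dim, len(class_names), bias=False, rng=rng)
        self.rff_dim = rff_dim
        self.mu = np.zeros(in_dim, dtype=np.float32)
        self.sd = np.ones(in_dim, dtype=np.float32)
        self.cov: np.ndarray | None = None  # Laplace posterior covariance

    # -- forward pieces ----------------------------------------------------
    def _features(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        xs = (np.asarray(x, np.float32) - self.mu) / self.sd
        h = self.trunk.forward(xs)
        self._pre_cos = h @ self.rff_w + self.rff_b
        phi = np.sqrt(2.0 / self.rff_dim) * np.cos(self._pre_cos)
        return phi.astype(np.float32)

    def _backward_features(self, dphi: np.ndarray) -> None:
        dpre = -np.sqrt(2.0 / self.rff_dim) * np.sin(self._pre_cos) * dphi
        self.trunk.backward((dpre @ self.rff_w.T).astype(np.float32))

    def raw_logits(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        phi = self._features(x)
        return phi @ self.beta.w, phi

    # -- prediction --------------------------------------------------------
    def predict_uncertainty(self, x: np.ndarray) -> UncertaintyOutput:
        if self.cov is None:
            raise RuntimeError("classifier not fitted (no Laplace covariance)")
        logits, phi = self.raw_logits(np.atleast_2d(x))
        var = np.einsum("nd,de,ne->n", phi, self.cov, phi)
        var = np.maximum(var, 0.0)
        adj = mean_field_adjust(logits, var, self.lam)
        u = dempster_shafer(adj)
        return UncertaintyOutput(self.class_names, logits, var, adj,
                                 np.atleast_1d(u), self.lam)

    def predict_output(self, x: np.ndarray) -> ClassifierOutput:
        out = self.predict_uncertainty(x)
        return ClassifierOutput(self.class_names, out.probabilities)

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.predict_uncertainty(x).predicted


def fit_sngp(embeddings: np.ndarray, labels, seed: int = 0, width: int = 128,
             rff_dim: int = 1024, lengthscale: float = 2.0,
             norm_bound: float = 0.95, ridge: float = 1.0,
             lam: float = MEAN_FIELD_LAMBDA, epochs: int = 60,
             batch_size: int = 64, lr: float = 1e-3) -> SNGPClassifier:
    """Train an SNGP classifier on in-distribution embeddings only."""
    x = np.asarray(embeddings, dtype=np.float32)
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    names = [str(c) for c in classes]
    y = np.searchsorted(classes, labels)
    model = SNGPClassifier(x.shape[1], names, width=width, rff_dim=rff_dim,
                           lengthscale=lengthscale, norm_bound=norm_bound,
                           ridge=ridge, lam=lam, seed=seed)
    model.mu = x.mean(axis=0).astype(np.float32)
    model.sd = (x.std(axis=0) + 1e-6).astype(np.float32)
    rng = np.random.default_rng(seed + 1)
    params = model.trunk.parameters() + model.beta.parameters()
    opt = Adam(params, lr=lr)
    n = len(x)
    for _ in range(epochs):
        order = rng.permutation(n)
        for i in range(0, n, batch_size):
            idx = order[i:i + batch_size]
            phi = model._features(x[idx], training=True)
            logits = model.beta.forward(phi)
            loss, dlogits = softmax_cross_entropy(logits, y[idx])
            dphi = model.beta.backward(dlogits)
            model._backward_features(dphi)
            opt.step()
            for sn in model.sn:
                sn.apply()
    # Laplace posterior precision over the GP weights (class-shared)
    precision = ridge * np.eye(model.rff_dim)
    for i in range(0, n, 256):
        phi = model._features(x[i:i + 256])
        logits = phi @ model.beta.w
        z = logits - logits.max(axis=1, keepdims=True)
        p = np.exp(z)
        p /= p.sum(axis=1, keepdims=True)
        pmax = p.max(axis=1)
        w = pmax * (1 - pmax)
        precision += (phi * w[:, None]).T @ phi
    model.cov = np.linalg.inv(precision)
    return model


# ---------------------------------------------------------------------------
# threshold calibration and the OOD evaluation protocol


class PlainUncertaintyAdapter:
    """Dempster-Shafer uncertainty on a plain classifier's raw logits.

    Gives unconstrained models (e.g. the ResNet-2 baseline) the same
    ``predict_uncertainty`` interface as the SNGP head, with zero
    predictive variance — the ablation without distance awareness.
    """

    def __init__(self, model):
        self.model = model
        self.class_names = model.class_names

    def predict_uncertainty(self, x: np.ndarray) -> UncertaintyOutput:
        logits = self.model.logits(np.atleast_2d(x))
        u = dempster_shafer(logits)
        return UncertaintyOutput(self.class_names, logits,
                                 np.zeros(len(logits)), logits,
                                 np.atleast_1d(u), 0.0)

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.predict_uncertainty(x).predicted


def calibrate_threshold(u_values: np.ndarray, is_ood: np.ndarray) -> tuple[float, float]:
    """Threshold on u maximizing F1 of the in- vs out-of-distribution task.

    Scans candidate thresholds at midpoints between sorted unique u
    values; an example is called OOD when its u exceeds the threshold.
    Ties resolve toward the smallest threshold. Returns (threshold, F1).
    """
    u = np.asarray(u_values, dtype=float)
    y = np.asarray(is_ood, dtype=bool)
    if not (y.any() and (~y).any()):
        raise ValueError("need both in- and out-of-distribution examples")
    uniq = np.unique(u)
    if len(uniq) < 2:
        raise ValueError("degenerate uncertainty values (all identical)")
    cands = (uniq[:-1] + uniq[1:]) / 2.0
    best_t, best_f1 = None, -1.0
    for t in cands:
        pred = u > t
        tp = np.sum(pred & y)
        fp = np.sum(pred & ~y)
        fn = np.sum(~pred & y)
        denom = 2 * tp + fp + fn
        f1 = 2 * tp / denom if denom else 0.0
        if f1 > best_f1 + 1e-12:
            best_t, best_f1 = float(t), float(f1)
    return best_t, best_f1


OOD_CLASS = "OOD"


@dataclass
class OODResult:
    class_names: list[str]      # in-distribution classes + OOD
    fold_f1: list[np.ndarray]   # per fold, per class (weighted)
    mean_f1: float
    thresholds: list[float]
    auroc: float


def auroc(scores: np.ndarray, positives: np.ndarray) -> float:
    """Rank-based AUROC of ``scores`` for the boolean ``positives``."""
    from scipy.stats import rankdata

    s = np.asarray(scores, float)
    y = np.asarray(positives, bool)
    r = rankdata(s)
    n_pos, n_neg = y.sum(), (~y).sum()
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need both classes for AUROC")
    return float((r[y].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def _weighted_f1(true, pred, weights, class_names) -> np.ndarray:
    k = len(class_names)
    index = {c: i for i, c in enumerate(class_names)}
    cm = np.zeros((k, k))
    for t, p, w in zip(true, pred, weights):
        cm[index[t], index[p]] += w
    return f1_from_confusion(cm)


def ood_protocol(in_embeddings: np.ndarray, in_labels, in_cell_ids,
                 ood_embeddings: np.ndarray, n_folds: int = 5, seed: int = 0,
                 classifier_factory=None,
                 threshold_override: float | None = None) -> OODResult:
    """Cross-validated out-of-distribution detection evaluation.

    Per fold: train on in-distribution cells only; score the held-out
    in-distribution embeddings plus the full OOD pool; calibrate the
    uncertainty threshold on a set-aside half of that test set; relabel
    predictions above the threshold as the OOD class; report class-wise
    F1 with examples weighted so the OOD class accounts for 50%, averaged
    over folds. Also reports the pooled AUROC of u for in vs out.

    ``threshold_override`` skips calibration and uses a fixed threshold
    (e.g. 1.0 to ablate uncertainty-based rejection entirely).
    """
    if classifier_factory is None:
        classifier_factory = lambda x, y, s: fit_sngp(x, y, seed=s)
    in_labels = np.asarray(in_labels).astype(str)
    in_cell_ids = np.asarray(in_cell_ids)
    classes = sorted(set(in_labels))
    if len(classes) < 2:
        raise ValueError("need at least 2 in-distribution classes")
    rng = np.random.default_rng(seed)
    cells = np.array(sorted(set(in_cell_ids.tolist())))
    cell_cls = np.array([in_labels[in_cell_ids == c][0] for c in cells])
    folds: list[set] = [set() for _ in range(n_folds)]
    for cls in classes:
        ids = cells[cell_cls == cls]
        if len(ids) < n_folds:
            raise ValueError(f"class {cls!r} has fewer cells than folds")
        perm = rng.permutation(len(ids))
        for j, i in enumerate(perm):
            folds[j % n_folds].add(ids[i])
    names = classes + [OOD_CLASS]
    fold_f1, thresholds = [], []
    all_u, all_ood_flag = [], []
    for fold in range(n_folds):
        test_cells = folds[fold]
        tr_mask = ~np.isin(in_cell_ids, list(test_cells))
        clf = classifier_factory(in_embeddings[tr_mask], in_labels[tr_mask],
                                 int(rng.integers(1 << 31)))
        te_idx = np.flatnonzero(~tr_mask)
        out_in = clf.predict_uncertainty(in_embeddings[te_idx])
        out_ood = clf.predict_uncertainty(ood_embeddings)
        u = np.concatenate([out_in.uncertainty, out_ood.uncertainty])
        pred = np.concatenate([out_in.predicted, out_ood.predicted]).astype(object)
        true = np.concatenate([in_labels[te_idx],
                               np.full(len(ood_embeddings), OOD_CLASS,
                                       dtype=object)])
        is_ood = np.concatenate([np.zeros(len(te_idx), bool),
                                 np.ones(len(ood_embeddings), bool)])
        # set aside half for threshold calibration
        half = rng.permutation(len(u)) < len(u) // 2
        if threshold_override is None:
            t, _ = calibrate_threshold(u[half], is_ood[half])
        else:
            t = float(threshold_override)
        thresholds.append(t)
        eval_mask = ~half
        pred_eval = pred[eval_mask].copy()
        pred_eval[u[eval_mask] > t] = OOD_CLASS
        true_eval = true[eval_mask]
        ood_eval = is_ood[eval_mask]
        n_in, n_out = int((~ood_eval).sum()), int(ood_eval.sum())
        weights = np.where(ood_eval, n_in / max(n_out, 1), 1.0)
        fold_f1.append(_weighted_f1(true_eval, pred_eval, weights, names))
        all_u.append(u)
        all_ood_flag.append(is_ood)
    mean_f1 = float(np.mean([f.mean() for f in fold_f1]))
    return OODResult(names, fold_f1, mean_f1, thresholds,
                     auroc(np.concatenate(all_u), np.concatenate(all_ood_flag)))
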