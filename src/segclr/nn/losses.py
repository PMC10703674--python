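"""Training losses with analytic gradients.

``nt_xent`` implements the normalized temperature-scaled cross-entropy
contrastive loss over a batch of 2N projection vectors arranged as N
positive pairs (rows 2i and 2i+1 are partners). Every other row in the
batch serves as a negative. ``decorrelation`` penalizes the mean squared
off-diagonal Pearson correlation between embedding dimensions over the
batch, pushing the embedding toward using its dimensions independently.
"""
from __future__ import annotations

import numpy as np

_EPS = 1e-12


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy over rows; returns (loss, dlogits)."""
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    p = ez / ez.sum(axis=1, keepdims=True)
    n = logits.shape[0]
    loss = -np.log(p[np.arange(n), labels] + _EPS).mean()
    dl = p.copy()
    dl[np.arange(n), labels] -= 1.0
    return float(loss), dl / n


def nt_xent(projections: np.ndarray, temperature: float = 0.1):
    """NT-Xent loss and gradient for interleaved positive pairs.

    Parameters
    ----------
    projections:
        (2N, d) array; rows 2i and 2i+1 form a positive pair.
    temperature:
        Softmax temperature tau > 0.

    Returns
    -------
    (loss, grad) with grad of the mean loss w.r.t. ``projections``.
    """
    z = np.asarray(projections, dtype=np.float64)
    if z.ndim != 2 or z.shape[0] < 4 or z.shape[0] % 2:
        raise ValueError("expected (2N, d) projections with N >= 2")
    norms = np.linalg.norm(z, axis=1, keepdims=True)
    if np.any(norms < _EPS):
        raise ValueError("zero-norm projection row")
    zn = z / norms
    m = z.shape[0]
    sim = zn @ zn.T / temperature
    np.fill_diagonal(sim, -np.inf)
    smax = sim.max(axis=1, keepdims=True)
    p = np.exp(sim - smax)
    rowsum = p.sum(axis=1, keepdims=True)
    p /= rowsum
    partner = np.arange(m) ^ 1
    # exact log-softmax (no epsilon): sim - (smax + log sum exp)
    logp = (sim[np.arange(m), partner] - smax[:, 0] - np.log(rowsum[:, 0]))
    loss = float(-logp.mean())
    # d(mean CE)/d(sim) = (P - Y)/m ; sim symmetric in zn
    y = np.zeros_like(p)
    y[np.arange(m), partner] = 1.0
    dsim = (p - y) / m
    dzn = (dsim + dsim.T) @ zn / temperature
    dz = (dzn - zn * (dzn * zn).sum(axis=1, keepdims=True)) / norms
    return loss, dz.astype(np.float32)


def nt_xent_loss(projections: np.ndarray, temperature: float = 0.1) -> float:
    """Scalar NT-Xent loss (see :func:`nt_xent`)."""
    return nt_xent(projections, temperature)[0]


def decorrelation(embeddings: np.ndarray):
    """Mean squared off-diagonal correlation of embedding dimensions.

    L = 1/(d^2 - d) * sum_{i != j} C_ij^2 where C is the Pearson
    correlation matrix of the d columns over the batch. Dimensions with
    zero variance contribute zero correlation (and zero gradient).

    Returns (loss, grad w.r.t. embeddings).
    """
    e = np.asarray(embeddings, dtype=np.float64)
    if e.ndim != 2 or e.shape[1] < 2:
        raise ValueError("expected (n, d) embeddings with d >= 2")
    if e.shape[0] < 2:
        raise ValueError("need at least 2 rows to estimate correlations")
    n, d = e.shape
    mu = e.mean(axis=0)
    c = e - mu
    std = np.sqrt((c ** 2).mean(axis=0))
    ok = std > _EPS
    zh = np.zeros_like(c)
    zh[:, ok] = c[:, ok] / std[ok]
    corr = zh.T @ zh / n
    np.fill_diagonal(corr, 0.0)
    denom = d * d - d
    loss = float((corr ** 2).sum() / denom)
    # dL/dC = 2 C / denom (off-diagonal); C symmetric
    g_corr = 2.0 * corr / denom
    dzh = zh @ (g_corr + g_corr.T) / n
    # back through per-column standardization zh = c/std, std = sqrt(mean c^2)
    de = np.zeros_like(e)
    inner = (dzh * zh).mean(axis=0)
    dc = np.zeros_like(c)
    dc[:, ok] = (dzh[:, ok] - zh[:, ok] * inner[ok]) / std[ok]
    de = dc - dc.mean(axis=0)
    return loss, de.astype(np.float32)


def decorrelation_loss(embeddings: np.ndarray) -> float:
    """Scalar decorrelation loss (see :func:`decorrelation`)."""
    return decorrelation(embeddings)[0]
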