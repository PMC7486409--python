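"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written by a different route than the
library code it checks: plain loops, finite differences, batched projected
gradient descent, exhaustive enumeration.
"""

from __future__ import annotations

import numpy as np


def auroc_pairwise(scores, labels) -> float:
    """AUROC by exhaustive positive-negative pair comparison (ties = 1/2)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (pos.size * neg.size)


def weighted_loss(R, W, H, alpha) -> np.ndarray:
    """Loss via the weighted-residual formulation (supports batched W, H)."""
    obs = (R > 0).astype(float)
    weights = alpha + (1.0 - alpha) * obs
    P = W @ H
    return 0.5 * np.sum(weights * (P - R) ** 2, axis=(-2, -1))


def pgd_best_loss(
    R: np.ndarray,
    alpha: float,
    k: int,
    n_restarts: int = 10_000,
    n_iter: int = 1_500,
    refine_top: int = 100,
    refine_iter: int = 10_000,
    seed: int = 0,
    init_high: float = 2.0,
) -> float:
    """Best loss over many random restarts of alternating projected gradient.

    Steps use conservative Lipschitz bounds (squared Frobenius norms), so
    every restart descends monotonically; the best few restarts are refined
    with extra iterations.
    """
    rng = np.random.default_rng(seed)
    n, m = R.shape
    obs = (R > 0).astype(float)
    weights = alpha + (1.0 - alpha) * obs

    def run(W, H, iters):
        for _ in range(iters):
            G = weights * (W @ H - R)
            gW = G @ np.swapaxes(H, -2, -1)
            stepW = 1.0 / (np.sum(H**2, axis=(-2, -1)) + 1e-12)
            W = np.maximum(W - stepW[:, None, None] * gW, 0.0)
            G = weights * (W @ H - R)
            gH = np.swapaxes(W, -2, -1) @ G
            stepH = 1.0 / (np.sum(W**2, axis=(-2, -1)) + 1e-12)
            H = np.maximum(H - stepH[:, None, None] * gH, 0.0)
        return W, H

    W = rng.uniform(0, init_high, size=(n_restarts, n, k))
    H = rng.uniform(0, init_high, size=(n_restarts, k, m))
    W, H = run(W, H, n_iter)
    losses = weighted_loss(R, W, H, alpha)
    top = np.argsort(losses)[:refine_top]
    Wt, Ht = run(W[top], H[top], refine_iter)
    return float(np.min(weighted_loss(R, Wt, Ht, alpha)))


def finite_diff_grads(R, W, H, alpha, h=1e-6):
    """Numerical gradients of the weighted loss w.r.t. every entry of W and H."""
    def f(Wx, Hx):
        return float(weighted_loss(R, Wx, Hx, alpha))

    gW = np.zeros_like(W)
    for idx in np.ndindex(W.shape):
        Wp, Wm = W.copy(), W.copy()
        Wp[idx] += h
        Wm[idx] -= h
        gW[idx] = (f(Wp, H) - f(Wm, H)) / (2 * h)
    gH = np.zeros_like(H)
    for idx in np.ndindex(H.shape):
        Hp, Hm = H.copy(), H.copy()
        Hp[idx] += h
        Hm[idx] -= h
        gH[idx] = (f(W, Hp) - f(W, Hm)) / (2 * h)
    return gW, gH


def classic_nmf_update(R, W, H, eps=1e-16):
    """Standard diagonally-rescaled multiplicative NMF update (W rule then H),
    written with explicit loops."""
    n, k = W.shape
    m = H.shape[1]
    Wn = W.copy()
    for i in range(n):
        for p in range(k):
            num = sum(R[i, j] * H[p, j] for j in range(m))
            den = sum(sum(W[i, q] * H[q, j] for q in range(k)) * H[p, j] for j in range(m))
            Wn[i, p] = W[i, p] * num / (den + eps)
    Hn = H.copy()
    for p in range(k):
        for j in range(m):
            num = sum(Wn[i, p] * R[i, j] for i in range(n))
            den = sum(Wn[i, p] * sum(Wn[i, q] * H[q, j] for q in range(k)) for i in range(n))
            Hn[p, j] = H[p, j] * num / (den + eps)
    return Wn, Hn


def step_auprc(scores, labels) -> float:
    """Step-wise (non-interpolated) area under the precision-recall curve."""
    order = np.argsort(-np.asarray(scores, dtype=float), kind="stable")
    y = np.asarray(labels)[order]
    tp = np.cumsum(y)
    precision = tp / np.arange(1, y.size + 1)
    return float(np.sum(precision * y) / y.sum())
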