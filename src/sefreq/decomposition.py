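"""Confidence-weighted non-negative matrix decomposition.

The model approximates the integer frequency-class matrix ``R`` by a product
of two non-negative low-rank factors, ``R ≈ W H``, where rows of ``W`` are
drug signatures and columns of ``H`` are side-effect signatures.  Unlike a
standard NMF on sparse ratings, *every* cell participates in the loss: the
observed cells (classes 1–5) carry full weight while the zero cells —
pairs for which no side effect was detected, which may be true negatives or
undetected associations — are down-weighted by a confidence ``alpha`` in
[0, 1]:

    L(W, H) = 1/2 ||M_obs ∘ (R − WH)||_F^2 + alpha/2 ||M_zero ∘ (WH)||_F^2,
    subject to W, H >= 0.

Minimisation uses diagonally-rescaled multiplicative updates whose fixed
points satisfy the KKT complementarity conditions of the constrained
problem; :func:`kkt_residual` measures distance from stationarity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .datamodel import FrequencyMatrix, ValidationError

__all__ = [
    "DecompositionConfig",
    "FactorModel",
    "loss",
    "update_step",
    "normalize_rows_h",
    "initial_factors",
    "fit",
    "predict_scores",
    "kkt_residual",
    "ConvergenceWarning",
]


class ConvergenceWarning(UserWarning):
    pass


@dataclass(frozen=True)
class DecompositionConfig:
    """Hyper-parameters of the decomposition.

    k : latent dimension (number of signature components).
    alpha : confidence weight on the zero cells, in [0, 1].
    epsilon : guard added to update denominators to prevent division by zero.
    tol_x : stopping tolerance on the max relative change of W and H entries.
    max_iter : iteration cap; hitting it warns and records the stop reason.
    init_low, init_high : range of the uniform random initialisation.
    seed : RNG seed for the initialisation.
    normalization : "compensated" rescales W columns so WH is invariant when
        H rows are unit-normalised each iteration; "h_only" is the literal
        H-only rescale; "none" disables normalisation.
    stop_metric : "max_entry" measures the relative change against the
        largest entry of the previous iterate (fast, converges in ~10^3
        iterations); "elementwise" measures every entry against itself —
        far stricter near zero, so runs continue until even near-zero
        entries stabilise (useful for stationarity studies), at the price
        of often reaching max_iter.
    """

    k: int = 10
    alpha: float = 0.05
    epsilon: float = 1e-16
    tol_x: float = 1e-3
    max_iter: int = 20_000
    init_low: float = 0.0
    init_high: float = 0.1
    seed: int = 0
    normalization: str = "compensated"
    stop_metric: str = "max_entry"

    def __post_init__(self):
        if not (0.0 <= self.alpha <= 1.0):
            raise ValidationError("alpha must lie in [0, 1]")
        if self.k < 1:
            raise ValidationError("k must be >= 1")
        if self.epsilon <= 0 or self.tol_x <= 0:
            raise ValidationError("epsilon and tol_x must be positive")
        if self.normalization not in ("compensated", "h_only", "none"):
            raise ValidationError(f"unknown normalization mode {self.normalization!r}")
        if self.stop_metric not in ("max_entry", "elementwise"):
            raise ValidationError(f"unknown stop metric {self.stop_metric!r}")


@dataclass
class FactorModel:
    """Fitted non-negative factors with their loss trace."""

    W: np.ndarray
    H: np.ndarray
    loss_trace: np.ndarray
    n_iter: int
    config: DecompositionConfig
    stop_reason: str = "converged"

    def __post_init__(self):
        if np.min(self.W) < 0 or np.min(self.H) < 0:
            raise ValidationError("factors must be non-negative")

    @property
    def k(self) -> int:
        return self.W.shape[1]

    def scores(self) -> np.ndarray:
        return predict_scores(self)


def _as_dense(matrix) -> np.ndarray:
    if isinstance(matrix, FrequencyMatrix):
        return matrix.values.astype(np.float64)
    return np.asarray(matrix, dtype=np.float64)


def _check_factors(W: np.ndarray, H: np.ndarray) -> None:
    if np.min(W) < 0 or np.min(H) < 0:
        raise ValidationError("W and H must be non-negative")


def _loss_from_product(R: np.ndarray, obs: np.ndarray, P: np.ndarray, alpha: float) -> float:
    fit_term = 0.5 * np.sum(np.where(obs, (R - P) ** 2, 0.0))
    zero_term = 0.5 * alpha * np.sum(np.where(obs, 0.0, P**2))
    return float(fit_term + zero_term)


def loss(matrix, W: np.ndarray, H: np.ndarray, alpha: float) -> float:
    """Weighted squared loss: fit on observed cells + alpha-weighted zeros."""
    R = _as_dense(matrix)
    _check_factors(W, H)
    return _loss_from_product(R, R > 0, W @ H, alpha)


def _weighted_product(P: np.ndarray, obs: np.ndarray, alpha: float) -> np.ndarray:
    # M_obs∘P + alpha·M_zero∘P, via the identity alpha·P + (1−alpha)·M_obs∘P
    return alpha * P + (1.0 - alpha) * np.where(obs, P, 0.0)


def update_step(matrix, W: np.ndarray, H: np.ndarray, alpha: float, epsilon: float = 1e-16):
    """One multiplicative update: the W rule, then the H rule with updated W.

    W <- W ∘ (R Hᵀ) / ((M_obs∘WH)Hᵀ + alpha (M_zero∘WH)Hᵀ + eps)
    H <- H ∘ (Wᵀ R) / (Wᵀ(M_obs∘WH) + alpha Wᵀ(M_zero∘WH) + eps)

    Both rules preserve non-negativity and never increase the loss (up to
    epsilon-order perturbation of the exact diagonally-rescaled step).
    """
    R = _as_dense(matrix)
    _check_factors(W, H)
    obs = R > 0
    P = W @ H
    W = W * (R @ H.T) / (_weighted_product(P, obs, alpha) @ H.T + epsilon)
    P = W @ H
    H = H * (W.T @ R) / (W.T @ _weighted_product(P, obs, alpha) + epsilon)
    return W, H


def normalize_rows_h(W: np.ndarray, H: np.ndarray, compensate: bool = True):
    """Scale each row of H to unit norm; optionally rescale W to keep WH fixed.

    Removes the diagonal-rescaling degeneracy W -> WΛ, H -> Λ⁻¹H.  All-zero
    rows of H are left untouched.
    """
    norms = np.linalg.norm(H, axis=1)
    safe = norms > 0
    scale = np.where(safe, norms, 1.0)
    H = H / scale[:, None]
    if compensate:
        W = W * scale[None, :]
    return W, H


def initial_factors(n: int, m: int, config: DecompositionConfig):
    """Uniform random initial W (n×k) and H (k×m) from the config seed."""
    rng = np.random.default_rng(config.seed)
    W = rng.uniform(config.init_low, config.init_high, size=(n, config.k))
    H = rng.uniform(config.init_low, config.init_high, size=(config.k, m))
    return W, H


def fit(matrix, config: DecompositionConfig | None = None, **overrides) -> FactorModel:
    """Fit the decomposition by iterated multiplicative updates.

    Starts from a uniform random initialisation in [init_low, init_high],
    alternates the W/H updates with per-iteration H-row normalisation, and
    stops when the relative change of the elements of W and H — the largest
    absolute entry change divided by the largest absolute entry of the
    previous iterate — drops below ``tol_x`` (or at ``max_iter``, with a
    warning).
    """
    if config is None:
        config = DecompositionConfig(**overrides)
    elif overrides:
        config = replace(config, **overrides)
    R = _as_dense(matrix)
    n, m = R.shape
    if n == 0 or m == 0:
        raise ValidationError("matrix must be non-empty")
    if config.k >= min(n, m):
        raise ValidationError(f"k={config.k} must be < min(n, m) = {min(n, m)}")
    obs = R > 0
    alpha, eps = config.alpha, config.epsilon
    W, H = initial_factors(n, m, config)
    compensate = config.normalization == "compensated"

    sqrt_eps = np.sqrt(np.finfo(float).eps)
    trace = []
    stop_reason = f"max_iter ({config.max_iter}) reached"
    it = 0
    for it in range(1, config.max_iter + 1):
        W_prev, H_prev = W, H
        P = W @ H
        W = W * (R @ H.T) / (_weighted_product(P, obs, alpha) @ H.T + eps)
        P = W @ H
        H = H * (W.T @ R) / (W.T @ _weighted_product(P, obs, alpha) + eps)
        P = W @ H
        if config.normalization != "none":
            W, H = normalize_rows_h(W, H, compensate=compensate)
        if not (np.all(np.isfinite(W)) and np.all(np.isfinite(H))):
            raise FloatingPointError(f"non-finite factor entries at iteration {it}")
        if config.normalization == "h_only":
            P = W @ H  # uncompensated rescale changes the product
        trace.append(_loss_from_product(R, obs, P, alpha))
        if config.stop_metric == "max_entry":
            dW = np.max(np.abs(W - W_prev)) / max(np.max(np.abs(W_prev)), sqrt_eps)
            dH = np.max(np.abs(H - H_prev)) / max(np.max(np.abs(H_prev)), sqrt_eps)
        else:
            dW = np.max(np.abs(W - W_prev) / np.maximum(np.abs(W_prev), eps))
            dH = np.max(np.abs(H - H_prev) / np.maximum(np.abs(H_prev), eps))
        if max(dW, dH) < config.tol_x:
            stop_reason = "converged"
            break
    if stop_reason != "converged":
        warnings.warn(
            f"decomposition did not converge within {config.max_iter} iterations",
            ConvergenceWarning,
            stacklevel=2,
        )
    return FactorModel(
        W=W,
        H=H,
        loss_trace=np.asarray(trace),
        n_iter=it,
        config=config,
        stop_reason=stop_reason,
    )


def predict_scores(model: FactorModel) -> np.ndarray:
    """Predicted score matrix R̂ = WH (non-negative reals)."""
    return model.W @ model.H


def kkt_residual(matrix, W: np.ndarray, H: np.ndarray, alpha: float) -> float:
    """KKT complementarity residual: max |min(X, dL/dX)| over entries of W, H.

    Zero at a stationary point of the non-negativity-constrained problem:
    either a variable is at the bound with non-negative gradient, or its
    gradient vanishes.
    """
    R = _as_dense(matrix)
    _check_factors(W, H)
    obs = R > 0
    P = W @ H
    D = np.where(obs, P - R, alpha * P)  # M_obs∘(P−R) + alpha·M_zero∘P
    grad_W = D @ H.T
    grad_H = W.T @ D
    rW = np.max(np.abs(np.minimum(W, grad_W)), initial=0.0)
    rH = np.max(np.abs(np.minimum(H, grad_H)), initial=0.0)
    return float(max(rW, rH))
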