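"""Stochastic neighbor embedding used to reorder correlated features.

This is the original (asymmetric, Gaussian-kernel) SNE: each point i gets a
row-conditional neighbor distribution P_i with per-point variance calibrated
so every P_i has the same perplexity (2^entropy), and low-dimensional
coordinates are found by gradient descent with momentum on
sum_i KL(P_i || Q_i), where Q is the row-conditional Gaussian distribution
of the embedded points (unit variance).

The only downstream consumer here is a feature *ordering*: features are
standardized, treated as points (the data matrix is transposed), embedded
into one dimension, and sorted along the embedding axis. Because Euclidean
distance between standardized feature vectors is monotone in
1 - Pearson correlation, neighboring positions in the order correspond to
highly correlated features.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .expression import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "SneConfig",
    "AffinityMatrix",
    "EmbeddingResult",
    "calibrate_variances",
    "conditional_affinities",
    "fit_embedding",
    "feature_order",
]


@dataclass
class SneConfig:
    output_dim: int = 1
    perplexity: float = 15.0
    learning_rate: float = 1.0
    momentum_early: float = 0.5
    momentum_late: float = 0.8
    momentum_switch_iter: int = 250
    max_iter: int = 1000
    init_scale: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.output_dim < 1:
            raise ValueError("output_dim must be >= 1")
        if self.perplexity <= 1:
            raise ValueError("perplexity must exceed 1")


@dataclass
class AffinityMatrix:
    """Row-conditional neighbor probabilities p_ij with calibrated variances."""

    p: np.ndarray
    variances: np.ndarray

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        self.variances = np.asarray(self.variances, dtype=float)
        n = self.p.shape[0]
        if self.p.shape != (n, n):
            raise ValueError("p must be square")
        if np.any(np.abs(np.diagonal(self.p)) > 0):
            raise ValueError("diagonal of p must be zero")
        if np.any((self.p < 0) | (self.p > 1)):
            raise ValueError("p entries must lie in [0, 1]")
        if np.any(np.abs(self.p.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError("each row of p must sum to 1")

    @property
    def n_points(self) -> int:
        return self.p.shape[0]


@dataclass
class EmbeddingResult:
    coordinates: np.ndarray
    kl_history: list[float]
    q: np.ndarray


def _row_entropy_bits(dist_row: np.ndarray, var: float) -> tuple[float, np.ndarray]:
    """Shannon entropy (bits) and probabilities of one Gaussian row."""
    logits = -dist_row / (2.0 * var)
    logits -= logits.max()
    w = np.exp(logits)
    total = w.sum()
    if total <= 0 or not np.isfinite(total):
        raise FloatingPointError("affinity row underflow; increase variance")
    p = w / total
    nz = p > 0
    entropy = -np.sum(p[nz] * np.log2(p[nz]))
    return entropy, p


def calibrate_variances(
    squared_distances: np.ndarray, perplexity: float, tol: float = 1e-3, max_steps: int = 64
) -> np.ndarray:
    """Per-row variance so each row distribution has the target perplexity.

    Bisection on log-variance; converges when 2^entropy is within ``tol``
    of the target (or the step budget is exhausted, keeping the closest).
    """
    d = np.asarray(squared_distances, dtype=float)
    n = d.shape[0]
    if d.shape != (n, n):
        raise ValueError("distance matrix must be square")
    if not np.all(np.isfinite(d)):
        raise ValueError("distances must be finite")
    if np.any(d < 0) or np.any(np.abs(np.diagonal(d)) > 0):
        raise ValueError("need nonnegative squared distances with zero diagonal")
    if not 1 < perplexity <= n - 1:
        raise ValueError(f"perplexity must lie in (1, {n - 1}], got {perplexity}")
    target = np.log2(perplexity)
    variances = np.empty(n)
    for i in range(n):
        row = np.delete(d[i], i)
        scale = np.mean(row)
        if scale == 0:  # coincident points: any variance gives uniform row
            variances[i] = 1.0
            continue
        lo, hi = None, None
        var = scale
        for _ in range(max_steps):
            entropy, _ = _row_entropy_bits(row, var)
            if abs(2.0 ** entropy - perplexity) < tol:
                break
            if entropy > target:  # too flat -> shrink variance
                hi = var
                var = var / 2.0 if lo is None else (lo + hi) / 2.0
            else:
                lo = var
                var = var * 2.0 if hi is None else (lo + hi) / 2.0
        variances[i] = var
    return variances


def conditional_affinities(points: np.ndarray, variances: np.ndarray) -> AffinityMatrix:
    """Row-conditional Gaussian affinities p_ij from point coordinates."""
    x = np.asarray(points, dtype=float)
    variances = np.asarray(variances, dtype=float)
    if np.any(variances <= 0):
        raise ValueError("variances must be positive")
    d = _pairwise_sq_dists(x)
    return _affinities_from_dists(d, variances)


def _pairwise_sq_dists(x: np.ndarray) -> np.ndarray:
    sq = np.sum(x * x, axis=1)
    d = sq[:, None] + sq[None, :] - 2.0 * (x @ x.T)
    np.fill_diagonal(d, 0.0)
    return np.maximum(d, 0.0)


def _affinities_from_dists(d: np.ndarray, variances: np.ndarray) -> AffinityMatrix:
    n = d.shape[0]
    p = np.empty_like(d)
    for i in range(n):
        logits = -d[i] / (2.0 * variances[i])
        logits[i] = -np.inf
        logits -= logits[np.arange(n) != i].max()
        w = np.exp(logits)
        total = w.sum()
        if total <= 0 or not np.isfinite(total):
            raise FloatingPointError(
                f"affinity row {i} underflowed; increase the variance"
            )
        p[i] = w / total
    return AffinityMatrix(p, variances)


def _q_conditional(y: np.ndarray) -> np.ndarray:
    """Row-conditional unit-variance Gaussian affinities of the embedding."""
    d = _pairwise_sq_dists(y)
    n = d.shape[0]
    q = np.empty_like(d)
    for i in range(n):
        logits = -d[i]
        logits[i] = -np.inf
        logits -= logits[np.arange(n) != i].max()
        w = np.exp(logits)
        q[i] = w / w.sum()
    return q


def _kl_rows(p: np.ndarray, q: np.ndarray) -> float:
    mask = p > 0
    qm = np.maximum(q, 1e-300)
    return float(np.sum(p[mask] * np.log(p[mask] / qm[mask])))


def fit_embedding(P: AffinityMatrix, config: SneConfig) -> EmbeddingResult:
    """Gradient descent with momentum on sum_i KL(P_i || Q_i).

    Deterministic given ``config.seed``; returns the best-so-far
    coordinates (the recorded KL history is the running minimum).
    """
    p = P.p
    n = P.n_points
    rng = np.random.default_rng(config.seed)
    y = rng.normal(scale=config.init_scale, size=(n, config.output_dim))
    velocity = np.zeros_like(y)
    best_y = y.copy()
    best_kl = np.inf
    history: list[float] = []
    step = config.learning_rate
    for it in range(config.max_iter):
        with np.errstate(over="raise", invalid="raise"):
            try:
                q = _q_conditional(y)
                kl = _kl_rows(p, q)
            except FloatingPointError:
                kl = np.inf
        if not np.isfinite(kl) and step < 1e-12:
            raise FloatingPointError(f"KL divergence became non-finite at iteration {it}")
        if kl < best_kl:
            best_kl = kl
            best_y = y.copy()
            step = min(step * 1.05, config.learning_rate)
        elif kl > best_kl * 1.05 or not np.isfinite(kl):
            # backtrack: the step overshot; restart from the best point with
            # a smaller step and no accumulated velocity
            y = best_y.copy()
            velocity[:] = 0.0
            step *= 0.5
            q = _q_conditional(y)
        history.append(best_kl)
        # asymmetric-SNE gradient: 2 sum_j (p_ij - q_ij + p_ji - q_ji)(y_i - y_j)
        coeff = p - q + p.T - q.T
        grad = 2.0 * (coeff.sum(axis=1)[:, None] * y - coeff @ y)
        momentum = (
            config.momentum_early if it < config.momentum_switch_iter else config.momentum_late
        )
        velocity = momentum * velocity - step * grad
        y = y + velocity
    q = _q_conditional(best_y)
    return EmbeddingResult(best_y, history, q)


def feature_order(X: ExpressionMatrix | np.ndarray, config: SneConfig | None = None) -> np.ndarray:
    """Permutation of feature indices sorted along a 1-D SNE embedding.

    Features are standardized across samples and embedded as points; the
    returned array lists original feature indices in embedding order (ties
    broken by original index). Constant features cannot be standardized and
    are placed last, preserving their relative order.
    """
    if config is None:
        config = SneConfig()
    values = X.values if isinstance(X, ExpressionMatrix) else np.asarray(X, dtype=float)
    n_feat = values.shape[0]
    if n_feat < 3:
        raise ValueError("need at least 3 features to build an order")
    sd = values.std(axis=1)
    constant = sd == 0
    if constant.any():
        logger.warning("feature_order: %d constant features placed last", int(constant.sum()))
    active = np.flatnonzero(~constant)
    if active.size < 3:
        return np.concatenate([active, np.flatnonzero(constant)])
    z = (values[active] - values[active].mean(axis=1, keepdims=True)) / sd[active, None]
    perplexity = min(config.perplexity, max(2.0, active.size / 3.0))
    d = _pairwise_sq_dists(z)
    variances = calibrate_variances(d, perplexity)
    P = _affinities_from_dists(d, variances)
    cfg = SneConfig(
        output_dim=1,
        perplexity=perplexity,
        learning_rate=config.learning_rate,
        momentum_early=config.momentum_early,
        momentum_late=config.momentum_late,
        momentum_switch_iter=config.momentum_switch_iter,
        max_iter=config.max_iter,
        init_scale=config.init_scale,
        seed=config.seed,
    )
    emb = fit_embedding(P, cfg)
    coord = emb.coordinates[:, 0]
    order_active = active[np.lexsort((active, coord))]
    return np.concatenate([order_active, np.flatnonzero(constant)])
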