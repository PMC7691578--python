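"""Self-contained (mu/mu_w, lambda) covariance matrix adaptation evolution strategy.

Candidate solutions are sampled from N(m, sigma^2 C). After ranking by the
objective, the mean moves to the weighted recombination of the mu best
solutions, the covariance receives a rank-one update along the evolution
path p_c plus a rank-mu update from the selected steps, and the step size
sigma adapts by cumulative step-size adaptation on the conjugate path
p_sigma. Learning rates default to the standard dimension-dependent
formulas (Hansen's tutorial); population-level parameters (lambda=200,
mu=100, sigma0=0.3, 200 generations) default to the values used for the
miRNA selection experiments.

The driver maximizes; rankings are therefore by descending objective.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["CmaesConfig", "CmaesState", "sample_population", "update_state", "maximize"]


def default_weights(mu: int) -> np.ndarray:
    """Log-rank recombination weights w_i proportional to ln(mu+1/2) - ln(i)."""
    w = np.log(mu + 0.5) - np.log(np.arange(1, mu + 1))
    return w / w.sum()


@dataclass
class CmaesConfig:
    dimension: int
    population_size: int = 200
    mu: int = 100
    sigma0: float = 0.3
    initial_mean: np.ndarray | float = 0.5
    max_generations: int = 200
    recombination_weights: np.ndarray | None = None
    c_1: float | None = None
    c_mu: float | None = None
    c_c: float | None = None
    c_sigma: float | None = None
    d_sigma: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        H = self.dimension
        if H < 1:
            raise ValueError("dimension must be positive")
        if not 1 <= self.mu <= self.population_size:
            raise ValueError("need 1 <= mu <= population size")
        if self.sigma0 <= 0:
            raise ValueError("sigma0 must be positive")
        if self.recombination_weights is None:
            self.recombination_weights = default_weights(self.mu)
        w = np.asarray(self.recombination_weights, dtype=float)
        if w.shape != (self.mu,) or np.any(w <= 0) or abs(w.sum() - 1) > 1e-12:
            raise ValueError("weights must be mu positive reals summing to 1")
        if np.any(np.diff(w) > 0):
            raise ValueError("weights must be nonincreasing")
        self.recombination_weights = w
        mu_eff = self.mu_eff
        if self.c_sigma is None:
            self.c_sigma = (mu_eff + 2.0) / (H + mu_eff + 5.0)
        if self.d_sigma is None:
            self.d_sigma = (
                1.0 + 2.0 * max(0.0, np.sqrt((mu_eff - 1.0) / (H + 1.0)) - 1.0) + self.c_sigma
            )
        if self.c_c is None:
            self.c_c = (4.0 + mu_eff / H) / (H + 4.0 + 2.0 * mu_eff / H)
        if self.c_1 is None:
            self.c_1 = 2.0 / ((H + 1.3) ** 2 + mu_eff)
        if self.c_mu is None:
            self.c_mu = min(
                1.0 - self.c_1,
                2.0 * (mu_eff - 2.0 + 1.0 / mu_eff) / ((H + 2.0) ** 2 + mu_eff),
            )
        for name in ("c_1", "c_mu", "c_c", "c_sigma"):
            rate = getattr(self, name)
            if not 0 <= rate <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {rate}")

    @property
    def mu_eff(self) -> float:
        w = np.asarray(self.recombination_weights)
        return float(1.0 / np.sum(w**2))


@dataclass
class CmaesState:
    """Mutable strategy state: mean, covariance, step size, evolution paths."""

    m: np.ndarray
    C: np.ndarray
    sigma: float
    p_c: np.ndarray
    p_sigma: np.ndarray
    generation: int = 0
    # eigendecomposition cache (B, sqrt eigenvalues) with a staleness counter
    _eigen_B: np.ndarray | None = None
    _eigen_d: np.ndarray | None = None
    _eigen_stale: int = 0

    @classmethod
    def initial(cls, config: CmaesConfig) -> "CmaesState":
        H = config.dimension
        m0 = np.asarray(config.initial_mean, dtype=float)
        if m0.ndim == 0:
            m0 = np.full(H, float(m0))
        if m0.shape != (H,):
            raise ValueError("initial_mean has wrong length")
        return cls(
            m=m0.copy(),
            C=np.eye(H),
            sigma=float(config.sigma0),
            p_c=np.zeros(H),
            p_sigma=np.zeros(H),
        )

    def check(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if np.max(np.abs(self.C - self.C.T)) >= 1e-10:
            raise ValueError("covariance lost symmetry")

    def eigen(self, refresh_every: int = 1) -> tuple[np.ndarray, np.ndarray]:
        """B and sqrt-eigenvalues of C, lazily refreshed.

        Decomposition is recomputed only when the cache is at least
        ``refresh_every`` updates old (factorization need not happen every
        generation); eigenvalues are clamped at 1e-14 to keep C positive
        definite under finite precision.
        """
        if self._eigen_B is None or self._eigen_stale >= refresh_every:
            vals, vecs = np.linalg.eigh((self.C + self.C.T) / 2.0)
            vals = np.maximum(vals, 1e-14)
            self._eigen_B = vecs
            self._eigen_d = np.sqrt(vals)
            self._eigen_stale = 0
        return self._eigen_B, self._eigen_d


def sample_population(
    state: CmaesState, population_size: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw lambda vectors m + sigma * B diag(d) z with z standard normal."""
    state.check()
    B, d = state.eigen()
    if np.any(~np.isfinite(d)) or np.any(d <= 0):
        raise ValueError("covariance is not positive definite after clamping")
    z = rng.standard_normal((population_size, state.m.size))
    return state.m + state.sigma * (z * d) @ B.T


def update_state(
    state: CmaesState, solutions: np.ndarray, config: CmaesConfig
) -> CmaesState:
    """One generation update from solutions ranked best-first.

    Mean: weighted recombination of the mu best. Path p_c: exponential
    smoothing of the normalized mean shift with normalizer
    sqrt(c_c (2 - c_c) mu_eff), which keeps the path stationary under
    neutral selection. Covariance: rank-one (p_c outer product) plus
    rank-mu (selected steps) update. Step size: cumulative step-size
    adaptation on p_sigma.
    """
    sols = np.asarray(solutions, dtype=float)
    mu = config.mu
    if sols.shape[0] < mu:
        raise ValueError(f"need at least mu={mu} ranked solutions, got {sols.shape[0]}")
    w = config.recombination_weights
    mu_eff = config.mu_eff
    H = config.dimension
    m_old, sigma = state.m, state.sigma

    m_new = w @ sols[:mu]
    y_w = (m_new - m_old) / sigma

    B, d = state.eigen()
    # C^{-1/2} y_w for the conjugate path
    c_inv_sqrt_y = B @ ((B.T @ y_w) / d)
    c_s, d_s = config.c_sigma, config.d_sigma
    p_sigma = (1 - c_s) * state.p_sigma + np.sqrt(c_s * (2 - c_s) * mu_eff) * c_inv_sqrt_y
    chi_n = np.sqrt(H) * (1 - 1 / (4 * H) + 1 / (21 * H**2))
    g = state.generation + 1

    c_c = config.c_c
    p_c = (1 - c_c) * state.p_c + np.sqrt(c_c * (2 - c_c) * mu_eff) * y_w

    ys = (sols[:mu] - m_old) / sigma
    rank_mu = (ys.T * w) @ ys
    C_new = (
        (1 - config.c_1 - config.c_mu) * state.C
        + config.c_1 * np.outer(p_c, p_c)
        + config.c_mu * rank_mu
    )
    C_new = (C_new + C_new.T) / 2.0

    sigma_new = sigma * np.exp((c_s / d_s) * (np.linalg.norm(p_sigma) / chi_n - 1.0))

    rates = config.c_1 + config.c_mu
    refresh = max(1, int(np.ceil(1.0 / (10.0 * H * rates)))) if rates > 0 else 1
    new = CmaesState(
        m=m_new,
        C=C_new,
        sigma=float(sigma_new),
        p_c=p_c,
        p_sigma=p_sigma,
        generation=g,
        _eigen_B=state._eigen_B,
        _eigen_d=state._eigen_d,
        _eigen_stale=state._eigen_stale + 1,
    )
    # honor the lazy refresh schedule by forcing refresh when due
    new.eigen(refresh_every=refresh)
    new.check()
    return new


def maximize(objective, config: CmaesConfig, budget: int | None = None):
    """Run the generation loop, maximizing ``objective``.

    Returns (best vector, best value, history of per-generation best-ever
    values). A non-finite objective value ranks that solution worst.
    ``budget`` caps the number of objective evaluations.
    """
    rng = np.random.default_rng(config.seed)
    state = CmaesState.initial(config)
    best_x: np.ndarray | None = None
    best_f = -np.inf
    history: list[float] = []
    evals = 0
    for _ in range(config.max_generations):
        if budget is not None and evals >= budget:
            break
        pop = sample_population(state, config.population_size, rng)
        values = np.empty(len(pop))
        for i, x in enumerate(pop):
            values[i] = objective(x)
        evals += len(pop)
        bad = ~np.isfinite(values)
        if bad.any():
            logger.warning("maximize: %d non-finite objective values ranked worst", bad.sum())
            values[bad] = -np.inf
        order = np.argsort(-values, kind="stable")
        gen_best = values[order[0]]
        if gen_best > best_f:
            best_f = float(gen_best)
            best_x = pop[order[0]].copy()
        history.append(best_f)
        state = update_state(state, pop[order], config)
    if best_x is None:
        raise ValueError("no generations executed; check budget and max_generations")
    return best_x, best_f, history
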