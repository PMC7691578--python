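"""Univariate Cox proportional-hazards evaluation of selected features.

The model is h(t, x) = h0(t) exp(x * beta) with an unspecified baseline
hazard h0. The coefficient beta is estimated by Newton-Raphson on the
Breslow-tie log partial likelihood; the standard error comes from the
observed information, the Wald p-value from a two-sided normal test, and
the hazard ratio is exp(beta). The cumulative baseline hazard uses
Breslow's estimator: at each distinct event time the increment is the
number of events there divided by the sum of exp(x * beta) over the risk
set, so S(t) = exp(-H0(t) exp(x beta)) = S0(t)^{exp(x beta)}.

Differential-expression direction calls (up/down regulation between tumor
and normal groups) use a two-group one-way ANOVA with Benjamini-Hochberg
FDR control across features.

Exposed statsmodels-style: ``UnivariateCox(...).fit()`` returns a
:class:`CoxResults` with estimates, uncertainty, and a summary table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "SurvivalRecord",
    "BaselineHazard",
    "RegulationResult",
    "UnivariateCox",
    "CoxResults",
    "fit_univariate_cox",
    "hazard_ratio_of",
    "breslow_baseline",
    "survival_function",
    "anova_regulation",
    "fdr_adjust",
    "cox_table",
]


@dataclass(frozen=True)
class SurvivalRecord:
    """Right-censored follow-up: event=1 is death, event=0 censoring."""

    time: float
    event: int

    def __post_init__(self) -> None:
        if self.time <= 0:
            raise ValueError("survival time must be positive")
        if self.event not in (0, 1):
            raise ValueError("event must be 0 or 1")


@dataclass
class BaselineHazard:
    """Breslow cumulative baseline hazard as a right-continuous step function."""

    event_times: np.ndarray
    increments: np.ndarray

    def __post_init__(self) -> None:
        self.event_times = np.asarray(self.event_times, dtype=float)
        self.increments = np.asarray(self.increments, dtype=float)
        if np.any(np.diff(self.event_times) <= 0):
            raise ValueError("event times must be strictly increasing")
        if np.any(self.increments < 0):
            raise ValueError("hazard increments must be nonnegative")

    def cumulative(self, t) -> np.ndarray | float:
        """H0(t): sum of increments at event times <= t (H0(0) = 0)."""
        t = np.asarray(t, dtype=float)
        csum = np.concatenate([[0.0], np.cumsum(self.increments)])
        idx = np.searchsorted(self.event_times, t, side="right")
        out = csum[idx]
        return float(out) if out.ndim == 0 else out


@dataclass
class RegulationResult:
    F_stat: float
    p_value: float
    fdr: float
    direction: str  # "up" | "down" | "not_significant"


def _unpack(records) -> tuple[np.ndarray, np.ndarray]:
    times = np.asarray([r.time for r in records], dtype=float)
    events = np.asarray([r.event for r in records], dtype=int)
    return times, events


def _breslow_loglik_derivs(
    beta: float, x: np.ndarray, times: np.ndarray, events: np.ndarray
) -> tuple[float, float, float]:
    """Log partial likelihood with Breslow ties, gradient and information.

    With events grouped at distinct event times t_k (d_k events, covariate
    sum s_k) and risk sets R_k = {j : t_j >= t_k}:
      l(beta) = sum_k [beta s_k - d_k log sum_{R_k} exp(x_j beta)].
    Computed in O(n log n) by sorting once and sweeping cumulative sums
    from the largest time down.
    """
    order = np.argsort(-times, kind="stable")
    xs, ts, es = x[order], times[order], events[order]
    eta = xs * beta
    shift = eta.max()
    w = np.exp(eta - shift)
    cw = np.cumsum(w)
    cwx = np.cumsum(w * xs)
    cwxx = np.cumsum(w * xs * xs)
    loglik = 0.0
    grad = 0.0
    info = 0.0
    i = 0
    n = len(ts)
    while i < n:
        j = i
        while j < n and ts[j] == ts[i]:
            j += 1
        # block [i, j) shares one time; risk set = everything up to j-1
        d = int(es[i:j].sum())
        if d > 0:
            s = float((xs[i:j] * es[i:j]).sum())
            S0 = cw[j - 1]
            S1 = cwx[j - 1]
            S2 = cwxx[j - 1]
            loglik += beta * s - d * (np.log(S0) + shift)
            grad += s - d * S1 / S0
            info += d * (S2 / S0 - (S1 / S0) ** 2)
        i = j
    return loglik, grad, info


def fit_univariate_cox(
    covariate, records, tol: float = 1e-8, max_iter: int = 50
) -> "CoxResults":
    """Newton-Raphson fit of the one-covariate Cox model (Breslow ties)."""
    x = np.asarray(covariate, dtype=float)
    times, events = _unpack(records)
    if x.shape != times.shape:
        raise ValueError("covariate and records must have equal length")
    if events.sum() < 2:
        raise ValueError("need at least two events to fit")
    if np.std(x) == 0:
        raise ValueError("covariate has zero variance")
    beta = 0.0
    converged = False
    iterations = 0
    loglik = np.nan
    for iterations in range(1, max_iter + 1):
        loglik, grad, info = _breslow_loglik_derivs(beta, x, times, events)
        if info <= 0:
            break
        step = grad / info
        # guard Newton overshoot on near-monotone likelihoods
        step = float(np.clip(step, -5.0, 5.0))
        beta += step
        if abs(step) < tol:
            converged = True
            break
    loglik, grad, info = _breslow_loglik_derivs(beta, x, times, events)
    se = 1.0 / np.sqrt(info) if info > 0 else np.inf
    # monotone likelihood (perfect separation) shows up as a runaway beta:
    # report it as non-converged rather than returning a spurious estimate
    converged = converged and np.isfinite(se) and abs(beta) <= 20
    z = beta / se if np.isfinite(se) and se > 0 else np.nan
    p = 2.0 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan
    return CoxResults(
        beta=float(beta),
        se=float(se),
        wald_z=float(z),
        p_value=float(p),
        log_partial_likelihood=float(loglik),
        iterations=iterations,
        converged=bool(converged),
        covariate=x,
        times=times,
        events=events,
    )


def hazard_ratio_of(beta: float) -> float:
    """Hazard ratio exp(beta); baseline-free under proportional hazards."""
    if not np.isfinite(beta):
        raise ValueError("beta must be finite")
    return float(np.exp(beta))


def breslow_baseline(covariate, records, beta: float) -> BaselineHazard:
    """Breslow estimator: increments d_k / sum_{risk set} exp(x_j beta)."""
    x = np.asarray(covariate, dtype=float)
    times, events = _unpack(records)
    order = np.argsort(-times, kind="stable")
    xs, ts, es = x[order], times[order], events[order]
    w = np.exp(xs * beta)
    cw = np.cumsum(w)
    out_t: list[float] = []
    out_h: list[float] = []
    i, n = 0, len(ts)
    while i < n:
        j = i
        while j < n and ts[j] == ts[i]:
            j += 1
        d = int(es[i:j].sum())
        if d > 0:
            out_t.append(float(ts[i]))
            out_h.append(d / cw[j - 1])
        i = j
    return BaselineHazard(np.asarray(out_t[::-1]), np.asarray(out_h[::-1]))


def survival_function(H0: BaselineHazard, linear_predictor: float):
    """S(t) = exp(-H0(t) exp(linear_predictor)) as a callable of time."""
    risk = np.exp(linear_predictor)

    def S(t):
        return np.exp(-H0.cumulative(t) * risk)

    return S


class UnivariateCox:
    """One-covariate Cox proportional-hazards model.

    Parameters
    ----------
    covariate : array-like
        Feature value (e.g. log2 expression) per subject.
    records : sequence of SurvivalRecord, or (times, events) arrays
    """

    def __init__(self, covariate, records, events=None):
        if events is not None:
            records = [SurvivalRecord(float(t), int(e)) for t, e in zip(records, events)]
        self.covariate = np.asarray(covariate, dtype=float)
        self.records = list(records)

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, covariate_col: str, duration_col: str, event_col: str
    ) -> "UnivariateCox":
        return cls(
            df[covariate_col].to_numpy(dtype=float),
            df[duration_col].to_numpy(dtype=float),
            df[event_col].to_numpy(dtype=int),
        )

    def fit(self, tol: float = 1e-8, max_iter: int = 50) -> "CoxResults":
        return fit_univariate_cox(self.covariate, self.records, tol=tol, max_iter=max_iter)


@dataclass
class CoxResults:
    """Fitted univariate Cox model: estimate, uncertainty, diagnostics."""

    beta: float
    se: float
    wald_z: float
    p_value: float
    log_partial_likelihood: float
    iterations: int
    converged: bool
    covariate: np.ndarray | None = None
    times: np.ndarray | None = None
    events: np.ndarray | None = None

    @property
    def hazard_ratio(self) -> float:
        return hazard_ratio_of(self.beta)

    def baseline_hazard(self) -> BaselineHazard:
        records = [SurvivalRecord(t, int(e)) for t, e in zip(self.times, self.events)]
        return breslow_baseline(self.covariate, records, self.beta)

    def predict_survival_function(self, covariate_value: float):
        H0 = self.baseline_hazard()
        return survival_function(H0, covariate_value * self.beta)

    def confint(self, alpha: float = 0.05) -> tuple[float, float]:
        q = stats.norm.ppf(1 - alpha / 2)
        return self.beta - q * self.se, self.beta + q * self.se

    def summary(self) -> str:
        lo, hi = self.confint()
        return "\n".join(
            [
                "Univariate Cox proportional hazards",
                "=" * 52,
                f"{'coef':>10}{'HR':>10}{'se':>10}{'z':>8}{'p':>12}",
                f"{self.beta:>10.4f}{self.hazard_ratio:>10.4f}{self.se:>10.4f}"
                f"{self.wald_z:>8.2f}{self.p_value:>12.3e}",
                f"95% CI for coef: [{lo:.4f}, {hi:.4f}]",
                f"converged: {self.converged} after {self.iterations} iterations",
                f"log partial likelihood: {self.log_partial_likelihood:.4f}",
            ]
        )


def anova_regulation(tumor, normal, alpha: float = 0.05) -> RegulationResult:
    """Two-group one-way ANOVA with an up/down direction call.

    Direction is "up" when the tumor mean exceeds the normal mean with
    p < alpha, "down" in the opposite significant case, otherwise
    "not_significant". Identical groups give F = 0, p = 1. The fdr field
    is filled by the caller after adjusting across features (defaults to
    the raw p here).
    """
    t = np.asarray(tumor, dtype=float)
    n = np.asarray(normal, dtype=float)
    if len(t) < 2 or len(n) < 2:
        raise ValueError("each group needs at least two values")
    if np.var(t) == 0 and np.var(n) == 0 and np.mean(t) == np.mean(n):
        F, p = 0.0, 1.0
    else:
        F, p = stats.f_oneway(t, n)
        F, p = float(F), float(p)
    if p < alpha:
        direction = "up" if np.mean(t) > np.mean(n) else "down"
    else:
        direction = "not_significant"
    return RegulationResult(F_stat=F, p_value=p, fdr=p, direction=direction)


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone-enforced)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def cox_table(
    expression: np.ndarray,
    feature_ids: list[str],
    times,
    events,
    tumor_mask=None,
) -> pd.DataFrame:
    """Per-feature univariate Cox fits as one tidy table.

    ``expression`` is features x samples aligned with ``times``/``events``.
    When ``tumor_mask`` marks tumor columns, regulation direction is called
    against the remaining (normal) columns and FDR is adjusted across
    features.
    """
    records = [SurvivalRecord(float(t), int(e)) for t, e in zip(times, events)]
    rows = []
    for fid, values in zip(feature_ids, np.asarray(expression, dtype=float)):
        fit = fit_univariate_cox(values, records)
        rows.append(
            {
                "feature": fid,
                "beta": fit.beta,
                "hazard_ratio": fit.hazard_ratio,
                "se": fit.se,
                "p": fit.p_value,
            }
        )
    df = pd.DataFrame(rows)
    df["fdr"] = fdr_adjust(df["p"].to_numpy())
    if tumor_mask is not None:
        tumor_mask = np.asarray(tumor_mask, dtype=bool)
        regs = [
            anova_regulation(vals[tumor_mask], vals[~tumor_mask])
            for vals in np.asarray(expression, dtype=float)
        ]
        reg_fdr = fdr_adjust([r.p_value for r in regs])
        df["anova_p"] = [r.p_value for r in regs]
        df["anova_fdr"] = reg_fdr
        df["direction"] = [r.direction for r in regs]
    return df
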