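"""Multi-run wrapper feature selection: optimization, ranking, finalization.

One run reorders features with a 1-D SNE embedding, then lets CMA-ES search
over threshold weight vectors whose decodes are scored by penalized
cross-validated classifier accuracy, keeping the elitist best subset.
Repeating the run R times with independent seeds yields a list L of best
subsets; features are ranked by how often they appear across runs
(frequency ranking), and a forward-selection pass over cumulative prefixes
of the ranked list picks the final subset with maximal CV accuracy.

The whole procedure is exposed statsmodels-style: build a
:class:`SubsetSelectionModel` from data and configuration, call ``fit()``,
and read estimates and diagnostics off the returned
:class:`SubsetSelectionResults`.

The module also carries the coverage expectation mathematics that justify
the number of runs: if each run reported S features drawn uniformly from D,
the expected number of distinct features seen after R runs is
D - D (1 - S/D)^R.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import cmaes, sne
from .expression import ExpressionMatrix, LabelVector
from .objective import (
    ClassifierSpec,
    DecoderConfig,
    FeatureSet,
    ObjectiveConfig,
    SubsetObjective,
    cv_accuracy,
)

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "RunResult",
    "RankedFeature",
    "CoverageParams",
    "SubsetSelectionModel",
    "SubsetSelectionResults",
    "run_once",
    "run_many",
    "rank_frequency",
    "forward_select",
    "expected_distinct",
    "expected_new_next_run",
]


@dataclass
class RunConfig:
    """Settings for the full multi-run selection procedure.

    Defaults follow the full-scale experimental profile (50 runs of 200
    generations with population 200). :meth:`desk` returns a scaled-down
    profile for interactive work and small synthetic studies.
    """

    n_runs: int = 50
    generations: int = 200
    population_size: int = 200
    mu: int = 100
    sigma0: float = 0.3
    threshold: float = 0.5
    alpha: float = 0.5
    upsilon: int = 10
    cv_folds: int = 5
    classifier: ClassifierSpec = field(default_factory=ClassifierSpec)
    sne: sne.SneConfig = field(default_factory=sne.SneConfig)
    decode_mode: str = "per_feature"
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_runs < 1:
            raise ValueError("need at least one run")

    @classmethod
    def desk(cls, **overrides) -> "RunConfig":
        """Scaled-down profile: R=10 runs, lambda=20, N=30 generations."""
        base = dict(n_runs=10, generations=30, population_size=20, mu=10)
        base.update(overrides)
        return cls(**base)

    def run_seeds(self) -> list[int]:
        """R distinct per-run seeds derived from the master seed."""
        ss = np.random.SeedSequence(self.master_seed)
        return [int(s) % (2**31) for s in ss.generate_state(self.n_runs)]


@dataclass
class RunResult:
    best_set: FeatureSet
    best_value: float
    trace: list[float]
    seed: int

    def __post_init__(self) -> None:
        if self.trace and abs(self.best_value - max(self.trace)) > 1e-12:
            raise ValueError("best_value must equal the maximum of the trace")


@dataclass
class RankedFeature:
    feature_index: int
    feature_id: str
    frequency: int
    mean_best_value: float


@dataclass
class CoverageParams:
    """Inputs of the uniform-selection coverage argument."""

    n_features: int = 199
    per_run: int = 10
    n_runs: int = 50

    def __post_init__(self) -> None:
        if not 0 < self.per_run <= self.n_features:
            raise ValueError("need 0 < per-run count <= total features")
        if self.n_runs < 0:
            raise ValueError("number of runs must be nonnegative")


def expected_distinct(p: CoverageParams) -> tuple[float, int]:
    """Expected number of distinct features reported at least once.

    E[distinct] = D - D (1 - S/D)^R under uniform selection of S features
    per run; returns the expectation and its integer part.
    """
    D, S, R = p.n_features, p.per_run, p.n_runs
    expectation = D - D * (1.0 - S / D) ** R
    return expectation, int(np.floor(expectation))


def expected_new_next_run(p: CoverageParams) -> float:
    """Expected count of never-seen features surfaced by one more run."""
    now, _ = expected_distinct(p)
    then, _ = expected_distinct(replace(p, n_runs=p.n_runs + 1))
    return then - now


def _build_components(X: ExpressionMatrix, y: LabelVector, cfg: RunConfig, seed: int):
    labels = y.aligned_to(X.sample_ids)
    ss = np.random.SeedSequence(seed)
    sne_seed, cma_seed, cv_seed = (int(s) % (2**31) for s in ss.generate_state(3))
    sne_cfg = replace(cfg.sne, seed=sne_seed)
    order = sne.feature_order(X, sne_cfg)
    decoder = DecoderConfig(
        n_features=X.n_features,
        feature_order=order,
        threshold=cfg.threshold,
        mode=cfg.decode_mode,
    )
    obj_cfg = ObjectiveConfig(
        n_features=X.n_features,
        alpha=cfg.alpha,
        upsilon=cfg.upsilon,
        cv_folds=cfg.cv_folds,
        cv_seed=cv_seed,
    )
    objective = SubsetObjective(X.values, labels, decoder, cfg.classifier, obj_cfg)
    cma_cfg = cmaes.CmaesConfig(
        dimension=decoder.n_weights,
        population_size=cfg.population_size,
        mu=cfg.mu,
        sigma0=cfg.sigma0,
        initial_mean=cfg.threshold,
        max_generations=cfg.generations,
        seed=cma_seed,
    )
    return objective, cma_cfg


def run_once(X: ExpressionMatrix, y: LabelVector, cfg: RunConfig, seed: int) -> RunResult:
    """One selection run: SNE reorder, CMA-ES search, elitist best subset.

    Best-of-run ties on objective value go to the smaller subset, then to
    the lexicographically smaller index tuple, so results are deterministic
    given the seed.
    """
    objective, cma_cfg = _build_components(X, y, cfg, seed)
    rng = np.random.default_rng(cma_cfg.seed)
    state = cmaes.CmaesState.initial(cma_cfg)
    best: tuple[float, int, tuple[int, ...]] | None = None
    best_set = FeatureSet(())
    trace: list[float] = []
    best_value = -np.inf
    for _ in range(cfg.generations):
        pop = cmaes.sample_population(state, cma_cfg.population_size, rng)
        values = np.array([objective(x) for x in pop])
        finite = np.where(np.isfinite(values), values, -np.inf)
        order = np.argsort(-finite, kind="stable")
        gen_max = finite[order[0]]
        # scan every individual tied at the generation maximum so that ties
        # resolve to the smaller, lexicographically first subset
        for idx in np.flatnonzero(finite == gen_max):
            S = objective.decode(pop[idx])
            key = (-finite[idx], len(S), S.indices)
            if best is None or key < best:
                best = key
                best_set = S
                best_value = float(finite[idx])
        trace.append(best_value)
        state = cmaes.update_state(state, pop[order], cma_cfg)
    return RunResult(best_set=best_set, best_value=best_value, trace=trace, seed=seed)


def run_many(
    X: ExpressionMatrix, y: LabelVector, cfg: RunConfig
) -> tuple[list[RunResult], list[FeatureSet]]:
    """R independent runs with distinct derived seeds; collects best sets.

    Failed runs are recorded and skipped; more than half failing is an
    error.
    """
    results: list[RunResult] = []
    failures: list[tuple[int, Exception]] = []
    for seed in cfg.run_seeds():
        try:
            results.append(run_once(X, y, cfg, seed))
        except Exception as exc:  # noqa: BLE001 - runs are isolated by design
            logger.error("run with seed %d failed: %s", seed, exc)
            failures.append((seed, exc))
    if len(results) < cfg.n_runs / 2:
        raise RuntimeError(
            f"only {len(results)} of {cfg.n_runs} runs succeeded; first error: {failures[0][1]}"
        )
    return results, [r.best_set for r in results]


def rank_frequency(
    L: list[FeatureSet],
    best_values: list[float] | None = None,
    feature_ids: list[str] | None = None,
) -> list[RankedFeature]:
    """Rank features by how many run-best subsets contain them.

    Primary key: frequency, descending. Ties: mean best objective value of
    the contributing runs, descending; then original feature index,
    ascending.
    """
    if not L:
        raise ValueError("empty list of feature sets")
    if best_values is None:
        best_values = [0.0] * len(L)
    freq: dict[int, int] = {}
    value_sum: dict[int, float] = {}
    for S, v in zip(L, best_values):
        for i in S:
            freq[i] = freq.get(i, 0) + 1
            value_sum[i] = value_sum.get(i, 0.0) + v
    ranked = sorted(freq, key=lambda i: (-freq[i], -(value_sum[i] / freq[i]), i))
    return [
        RankedFeature(
            feature_index=i,
            feature_id=feature_ids[i] if feature_ids else str(i),
            frequency=freq[i],
            mean_best_value=value_sum[i] / freq[i],
        )
        for i in ranked
    ]


def forward_select(
    ranked: list[int] | list[RankedFeature],
    X: ExpressionMatrix | np.ndarray,
    y,
    clf: ClassifierSpec,
    cfg: ObjectiveConfig,
) -> tuple[FeatureSet, list[float]]:
    """Cumulative-prefix forward selection over the ranked feature list.

    Scores every prefix ranked[:k] by CV accuracy and returns the prefix
    with the maximum (ties to the shortest prefix) plus the full accuracy
    curve.
    """
    indices = [r.feature_index if isinstance(r, RankedFeature) else int(r) for r in ranked]
    if not indices:
        raise ValueError("ranked list is empty")
    cache: dict = {}
    curve = [
        cv_accuracy(X, y, FeatureSet(indices[:k]), clf, cfg, cache)
        for k in range(1, len(indices) + 1)
    ]
    best_k = int(np.argmax(curve)) + 1  # argmax takes the first maximum
    return FeatureSet(indices[:best_k]), curve


class SubsetSelectionModel:
    """Wrapper feature-selection model over labeled expression data.

    Parameters
    ----------
    X : ExpressionMatrix
        Preprocessed (log2-scale) feature-by-sample expression.
    y : LabelVector
        Class labels covering the samples of ``X``.
    config : RunConfig
        Procedure settings; ``RunConfig.desk()`` gives a scaled-down
        profile.
    """

    def __init__(self, X: ExpressionMatrix, y: LabelVector, config: RunConfig | None = None):
        self.X = X
        self.y = y
        self.config = config or RunConfig()
        labels = y.aligned_to(X.sample_ids)
        if len(np.unique(labels)) < 2:
            raise ValueError("classification needs at least two classes")

    @classmethod
    def from_dataframe(
        cls, expression: pd.DataFrame, labels: pd.Series, config: RunConfig | None = None
    ) -> "SubsetSelectionModel":
        """Build from a features-x-samples DataFrame and a label Series."""
        X = ExpressionMatrix(
            [str(i) for i in expression.index],
            [str(c) for c in expression.columns],
            expression.to_numpy(dtype=float),
            scale_tag="log2",
        )
        lab = labels.reindex(expression.columns)
        y = LabelVector([str(s) for s in lab.index], [str(v) for v in lab.to_numpy()])
        return cls(X, y, config)

    def fit(self) -> "SubsetSelectionResults":
        cfg = self.config
        runs, L = run_many(self.X, self.y, cfg)
        ranking = rank_frequency(
            L, [r.best_value for r in runs], feature_ids=self.X.feature_ids
        )
        labels = self.y.aligned_to(self.X.sample_ids)
        obj_cfg = ObjectiveConfig(
            n_features=self.X.n_features,
            alpha=cfg.alpha,
            upsilon=cfg.upsilon,
            cv_folds=cfg.cv_folds,
            cv_seed=int(np.random.SeedSequence(cfg.master_seed).generate_state(1)[0] % 2**31),
        )
        selected, curve = forward_select(
            ranking, self.X.values, labels, cfg.classifier, obj_cfg
        )
        return SubsetSelectionResults(self, runs, ranking, selected, curve)


class SubsetSelectionResults:
    """Fitted selection results: runs, ranking, final subset, diagnostics."""

    def __init__(self, model, runs, ranking, selected, prefix_accuracy):
        self.model = model
        self.runs: list[RunResult] = runs
        self.ranking: list[RankedFeature] = ranking
        self.selected: FeatureSet = selected
        self.prefix_accuracy: list[float] = prefix_accuracy

    @property
    def selected_ids(self) -> list[str]:
        return [self.model.X.feature_ids[i] for i in self.selected]

    @property
    def best_accuracy(self) -> float:
        return max(self.prefix_accuracy)

    def ranking_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature_id": [r.feature_id for r in self.ranking],
                "feature_index": [r.feature_index for r in self.ranking],
                "frequency": [r.frequency for r in self.ranking],
                "mean_best_value": [r.mean_best_value for r in self.ranking],
            }
        )

    def prefix_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "prefix_length": np.arange(1, len(self.prefix_accuracy) + 1),
                "feature_id": [r.feature_id for r in self.ranking],
                "cv_accuracy": self.prefix_accuracy,
            }
        )

    def manifest(self) -> dict:
        """JSON-serializable record of seeds and per-run traces for replay."""
        return {
            "master_seed": self.model.config.master_seed,
            "runs": [
                {
                    "seed": r.seed,
                    "best_value": r.best_value,
                    "best_set": list(r.best_set),
                    "trace": r.trace,
                }
                for r in self.runs
            ],
            "selected": list(self.selected),
        }

    def summary(self) -> str:
        cfg = self.model.config
        lines = [
            "Subset selection results",
            "=" * 56,
            f"runs: {len(self.runs)}  generations: {cfg.generations}  "
            f"population: {cfg.population_size}",
            f"classifier: {cfg.classifier.kind}  cv folds: {cfg.cv_folds}",
            f"selected {len(self.selected)} features "
            f"(cv accuracy {self.best_accuracy:.4f}):",
            "  " + ", ".join(self.selected_ids),
            "",
            "top of frequency ranking:",
            f"{'feature':<20}{'freq':>6}{'mean value':>12}",
        ]
        for r in self.ranking[:10]:
            lines.append(f"{r.feature_id:<20}{r.frequency:>6}{r.mean_best_value:>12.4f}")
        return "\n".join(lines)
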