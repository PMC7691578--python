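import numpy as np
import pytest

from evosel.expression import ExpressionMatrix, LabelVector
from evosel.objective import ClassifierSpec, FeatureSet, ObjectiveConfig, cv_accuracy
from evosel.selection import (
    CoverageParams,
    RunConfig,
    SubsetSelectionModel,
    expected_distinct,
    expected_new_next_run,
    forward_select,
    rank_frequency,
    run_many,
    run_once,
)
from evosel.simulate import ExpressionSimDesign, simulate_expression


def small_cfg(seed=0, **kw):
    base = dict(
        n_runs=2, generations=8, population_size=12, mu=6,
        classifier=ClassifierSpec(kind="knn"), upsilon=4, master_seed=seed,
    )
    base.update(kw)
    return RunConfig(**base)


@pytest.fixture(scope="module")
def planted_small():
    design = ExpressionSimDesign(
        n_classes=3, samples_per_class=20, n_features=20,
        informative_per_class=1, effect_delta=3.0, seed=11,
    )
    return simulate_expression(design)


class TestCoverage:
    def test_full_scale_values(self):
        p = CoverageParams(n_features=199, per_run=10, n_runs=50)
        expectation, integer_part = expected_distinct(p)
        assert integer_part == 183
        assert round(expected_new_next_run(p)) == 1

    def test_zero_runs(self):
        p = CoverageParams(n_features=50, per_run=5, n_runs=0)
        assert expected_distinct(p) == (0.0, 0)
        assert expected_new_next_run(p) == pytest.approx(5.0)

    def test_full_selection_certain_coverage(self):
        p = CoverageParams(n_features=30, per_run=30, n_runs=1)
        expectation, integer_part = expected_distinct(p)
        assert expectation == pytest.approx(30.0)

    def test_nondecreasing_and_concave_in_runs(self):
        values = [
            expected_distinct(CoverageParams(n_features=80, per_run=7, n_runs=r))[0]
            for r in range(0, 40)
        ]
        diffs = np.diff(values)
        assert np.all(diffs >= -1e-12)
        assert np.all(np.diff(diffs) <= 1e-12)

    def test_monte_carlo_agrees_with_closed_form(self):
        rng = np.random.default_rng(0)
        D, S, R, reps = 40, 6, 12, 10000
        counts = np.empty(reps)
        for k in range(reps):
            seen = set()
            for _ in range(R):
                seen.update(rng.choice(D, size=S, replace=False))
            counts[k] = len(seen)
        expectation, _ = expected_distinct(CoverageParams(D, S, R))
        se = counts.std(ddof=1) / np.sqrt(reps)
        assert abs(counts.mean() - expectation) < 3 * se


class TestRankFrequency:
    def test_hand_example(self):
        L = [FeatureSet([0, 1]), FeatureSet([1, 2]), FeatureSet([1])]
        ranked = rank_frequency(L)
        assert [r.feature_index for r in ranked] == [1, 0, 2]
        assert [r.frequency for r in ranked] == [3, 1, 1]

    def test_identical_sets_in_index_order(self):
        L = [FeatureSet([4, 2, 9])] * 3
        ranked = rank_frequency(L)
        assert [r.feature_index for r in ranked] == [2, 4, 9]

    def test_tie_broken_by_mean_best_value(self):
        L = [FeatureSet([0]), FeatureSet([1])]
        ranked = rank_frequency(L, best_values=[0.5, 0.9])
        assert [r.feature_index for r in ranked] == [1, 0]

    def test_frequencies_match_counting_oracle(self):
        rng = np.random.default_rng(1)
        L = [FeatureSet(rng.choice(30, size=rng.integers(1, 8), replace=False)) for _ in range(100)]
        ranked = rank_frequency(L)
        for r in ranked:
            assert r.frequency == sum(r.feature_index in S for S in L)
        assert sorted(r.feature_index for r in ranked) == sorted({i for S in L for i in S})


class TestForwardSelect:
    def test_tie_takes_smallest_prefix(self, monkeypatch):
        accs = {1: 0.6, 2: 0.9, 3: 0.9, 4: 0.85}
        monkeypatch.setattr(
            "evosel.selection.cv_accuracy",
            lambda X, y, S, clf, cfg, cache=None: accs[len(S)],
        )
        S, curve = forward_select(
            [7, 3, 5, 1], None, None, ClassifierSpec(), ObjectiveConfig(n_features=10)
        )
        assert S.indices == (3, 7)  # prefix of length 2 wins the tie
        assert curve == [0.6, 0.9, 0.9, 0.85]

    def test_strictly_increasing_curve_keeps_full_list(self, monkeypatch):
        monkeypatch.setattr(
            "evosel.selection.cv_accuracy",
            lambda X, y, S, clf, cfg, cache=None: 0.1 * len(S),
        )
        S, _ = forward_select(
            [2, 0, 4], None, None, ClassifierSpec(), ObjectiveConfig(n_features=5)
        )
        assert S.indices == (0, 2, 4)

    def test_matches_bruteforce_prefix_oracle(self, planted_small):
        X, y, truth = planted_small
        labels = y.aligned_to(X.sample_ids)
        planted = [X.feature_ids.index(ids[0]) for ids in truth.values()]
        ranked = planted + [10, 15]
        clf = ClassifierSpec(kind="knn")
        cfg = ObjectiveConfig(n_features=X.n_features)
        S, curve = forward_select(ranked, X.values, labels, clf, cfg)
        oracle = [
            cv_accuracy(X.values, labels, FeatureSet(ranked[:k]), clf, cfg)
            for k in range(1, len(ranked) + 1)
        ]
        np.testing.assert_allclose(curve, oracle, atol=1e-12)
        best_k = int(np.argmax(oracle)) + 1
        assert S.indices == FeatureSet(ranked[:best_k]).indices

    def test_empty_list_rejected(self, planted_small):
        X, y, _ = planted_small
        with pytest.raises(ValueError, match="empty"):
            forward_select([], X.values, y.aligned_to(X.sample_ids),
                           ClassifierSpec(), ObjectiveConfig(n_features=X.n_features))


class TestRuns:
    def test_run_once_trace_nondecreasing(self, planted_small):
        X, y, _ = planted_small
        res = run_once(X, y, small_cfg(), seed=123)
        assert np.all(np.diff(res.trace) >= 0)
        assert res.best_value == max(res.trace)
        assert len(res.trace) == small_cfg().generations

    def test_run_once_deterministic(self, planted_small):
        X, y, _ = planted_small
        a = run_once(X, y, small_cfg(), seed=55)
        b = run_once(X, y, small_cfg(), seed=55)
        assert a.best_set.indices == b.best_set.indices
        assert a.trace == b.trace

    def test_single_generation_boundary(self, planted_small):
        X, y, _ = planted_small
        res = run_once(X, y, small_cfg(generations=1), seed=9)
        assert len(res.trace) == 1

    def test_run_many_collects_best_sets(self, planted_small):
        X, y, _ = planted_small
        results, L = run_many(X, y, small_cfg(seed=3))
        assert len(results) == 2 and len(L) == 2
        assert all(r.best_set.indices == s.indices for r, s in zip(results, L))

    def test_recovers_planted_features(self, planted_small):
        X, y, truth = planted_small
        planted = {X.feature_ids.index(ids[0]) for ids in truth.values()}
        hits = 0
        for seed in range(5):
            res = run_once(X, y, small_cfg(generations=15, population_size=16, mu=8), seed=seed)
            hits += len(planted & set(res.best_set.indices)) >= 2
        assert hits >= 4


class TestModelApi:
    def test_fit_returns_consistent_results(self, planted_small):
        X, y, truth = planted_small
        res = SubsetSelectionModel(X, y, small_cfg(seed=21)).fit()
        assert len(res.runs) == 2
        assert len(res.prefix_accuracy) == len(res.ranking)
        assert res.best_accuracy == max(res.prefix_accuracy)
        assert set(res.selected.indices) <= {r.feature_index for r in res.ranking}
        text = res.summary()
        assert "selected" in text and "frequency" in text
        manifest = res.manifest()
        assert len(manifest["runs"]) == 2

    def test_single_class_rejected(self):
        X = ExpressionMatrix(["f1", "f2", "f3"], ["s1", "s2"], np.zeros((3, 2)), "log2")
        y = LabelVector(["s1", "s2"], ["A", "A"])
        with pytest.raises(ValueError, match="two classes"):
            SubsetSelectionModel(X, y, small_cfg())

    def test_from_dataframe_round_trip(self, planted_small):
        import pandas as pd

        X, y, _ = planted_small
        df = X.to_frame()
        labels = pd.Series(y.labels, index=y.sample_ids)
        model = SubsetSelectionModel.from_dataframe(df, labels, small_cfg())
        assert model.X.feature_ids == X.feature_ids
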