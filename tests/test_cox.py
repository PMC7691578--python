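import numpy as np
import pytest

from evosel.cox import (
    BaselineHazard,
    SurvivalRecord,
    UnivariateCox,
    anova_regulation,
    breslow_baseline,
    cox_table,
    fdr_adjust,
    fit_univariate_cox,
    hazard_ratio_of,
    survival_function,
)
from evosel.simulate import SurvivalSimDesign, simulate_survival


def toy_records():
    times = [5.0, 8.0, 12.0, 20.0, 25.0, 33.0, 40.0, 50.0]
    return [SurvivalRecord(t, 1) for t in times]


def grid_search_beta(covariate, records, lo=-5.0, hi=5.0, step=1e-4):
    """Brute-force maximizer of the Breslow log partial likelihood."""
    x = np.asarray(covariate, dtype=float)
    times = np.array([r.time for r in records])
    events = np.array([r.event for r in records])
    order = np.argsort(times)
    x, times, events = x[order], times[order], events[order]

    def loglik(beta):
        ll = 0.0
        for k in np.flatnonzero(events):
            risk = times >= times[k]
            ll += x[k] * beta - np.log(np.sum(np.exp(x[risk] * beta)))
        return ll

    grid = np.arange(lo, hi + step, step)
    values = [loglik(b) for b in grid]
    return grid[int(np.argmax(values))]


class TestFit:
    def test_matches_grid_oracle_on_toy_data(self):
        x = [1.0, 0.0, 1.0, 0.0, 1.0, 0.0, 0.0, 1.0]
        records = toy_records()
        fit = fit_univariate_cox(x, records)
        assert fit.converged
        assert abs(fit.beta - grid_search_beta(x, records)) < 1e-3

    def test_matches_lifelines_on_tie_free_data(self):
        import pandas as pd
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(0)
        x = rng.normal(size=120)
        times = rng.exponential(20, 120) * np.exp(-0.5 * x)  # continuous: no ties
        events = rng.random(120) < 0.8
        records = [SurvivalRecord(float(t), int(e)) for t, e in zip(times, events)]
        fit = fit_univariate_cox(x, records)
        df = pd.DataFrame({"x": x, "t": [r.time for r in records], "e": [r.event for r in records]})
        cph = CoxPHFitter().fit(df, "t", "e")
        assert fit.beta == pytest.approx(float(cph.params_["x"]), abs=1e-6)
        assert fit.se == pytest.approx(float(cph.standard_errors_["x"]), abs=1e-6)
        assert fit.p_value == pytest.approx(float(cph.summary.loc["x", "p"]), abs=1e-6)

    def test_tied_times_match_breslow_grid_oracle(self):
        rng = np.random.default_rng(12)
        x = rng.normal(size=40)
        # heavy discretization creates ties; censoring mixed in
        times = np.ceil(rng.exponential(5, 40) * np.exp(-0.6 * x)) + 1
        events = rng.random(40) < 0.8
        events[:2] = True
        records = [SurvivalRecord(float(t), int(e)) for t, e in zip(times, events)]
        fit = fit_univariate_cox(x, records)
        assert abs(fit.beta - grid_search_beta(x, records)) < 1e-3

    def test_zero_variance_covariate_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            fit_univariate_cox(np.ones(8), toy_records())

    def test_too_few_events_rejected(self):
        records = [SurvivalRecord(t, 0) for t in [1.0, 2.0, 3.0]]
        with pytest.raises(ValueError, match="two events"):
            fit_univariate_cox([0.0, 1.0, 2.0], records)

    def test_perfect_separation_flagged(self):
        # covariate perfectly orders the times: monotone likelihood
        x = np.arange(12, dtype=float)
        records = [SurvivalRecord(float(12 - i), 1) for i in range(12)]
        fit = fit_univariate_cox(x, records)
        assert not fit.converged

    def test_time_scaling_leaves_beta_unchanged(self):
        rng = np.random.default_rng(1)
        x, records = simulate_survival(SurvivalSimDesign(n=150, beta_true=0.4, seed=2))
        fit1 = fit_univariate_cox(x, records)
        scaled = [SurvivalRecord(r.time * 365.25, r.event) for r in records]
        fit2 = fit_univariate_cox(x, scaled)
        assert fit1.beta == pytest.approx(fit2.beta, abs=1e-9)

    def test_centering_covariate_leaves_beta_unchanged(self):
        x, records = simulate_survival(SurvivalSimDesign(n=150, beta_true=0.4, seed=3))
        fit1 = fit_univariate_cox(x, records)
        fit2 = fit_univariate_cox(x - x.mean() + 7.0, records)
        assert fit1.beta == pytest.approx(fit2.beta, abs=1e-8)


class TestHazardRatio:
    def test_null_effect(self):
        assert hazard_ratio_of(0.0) == 1.0

    @pytest.mark.parametrize(
        "beta,hr", [(0.8083, 2.2441), (0.1731, 1.1890)]
    )
    def test_printed_coefficient_identities(self, beta, hr):
        assert hazard_ratio_of(beta) == pytest.approx(hr, abs=1e-4)

    def test_results_object_consistency(self):
        x, records = simulate_survival(SurvivalSimDesign(n=100, beta_true=0.5, seed=4))
        fit = UnivariateCox(x, records).fit()
        assert fit.hazard_ratio == pytest.approx(np.exp(fit.beta), abs=1e-12)
        assert "Cox" in fit.summary()


class TestBreslow:
    def test_single_event_closed_form(self):
        # beta=0: increment at the first event time is 1/(n at risk)
        records = [SurvivalRecord(t, int(t == 5.0)) for t in [5.0, 10.0, 15.0, 20.0]]
        H0 = breslow_baseline(np.array([0.1, 0.2, 0.3, 0.4]), records, beta=0.0)
        assert H0.increments[0] == pytest.approx(1 / 4)
        assert H0.cumulative(4.9) == 0.0
        assert H0.cumulative(5.0) == pytest.approx(1 / 4)

    def test_no_events_zero_function(self):
        records = [SurvivalRecord(t, 0) for t in [1.0, 2.0, 3.0]]
        H0 = breslow_baseline(np.zeros(3) + [0, 1, 2], records, beta=0.3)
        assert H0.event_times.size == 0
        assert H0.cumulative(100.0) == 0.0

    def test_cumulative_nondecreasing_random_inputs(self):
        x, records = simulate_survival(SurvivalSimDesign(n=200, beta_true=0.3, seed=5))
        fit = fit_univariate_cox(x, records)
        H0 = breslow_baseline(x, records, fit.beta)
        t = np.linspace(0, max(r.time for r in records), 200)
        assert np.all(np.diff(H0.cumulative(t)) >= 0)


class TestSurvivalFunction:
    def test_zero_hazard_gives_unit_survival(self):
        H0 = BaselineHazard(np.array([1.0, 2.0]), np.array([0.0, 0.0]))
        S = survival_function(H0, 1.3)
        assert S(10.0) == 1.0

    def test_zero_predictor_equals_baseline(self):
        H0 = BaselineHazard(np.array([1.0, 3.0]), np.array([0.2, 0.4]))
        S = survival_function(H0, 0.0)
        assert S(3.5) == pytest.approx(np.exp(-0.6))

    def test_both_algebraic_forms_agree(self):
        rng = np.random.default_rng(6)
        H0 = BaselineHazard(np.sort(rng.uniform(0, 10, 5)), rng.uniform(0, 0.5, 5))
        lp = 0.73
        S = survival_function(H0, lp)
        for t in rng.uniform(0, 12, 20):
            s0 = np.exp(-H0.cumulative(t))
            assert S(t) == pytest.approx(s0 ** np.exp(lp), abs=1e-12)


class TestRegulation:
    def test_identical_groups_not_significant(self):
        g = [1.0, 2.0, 3.0]
        res = anova_regulation(g, g)
        assert res.direction == "not_significant"
        assert res.F_stat == 0.0

    def test_large_shift_called_up(self):
        rng = np.random.default_rng(7)
        normal = rng.normal(0, 1, 20)
        res = anova_regulation(normal + 5.0, normal)
        assert res.direction == "up"
        assert res.p_value < 0.05

    def test_f_equals_t_squared(self):
        from scipy import stats

        rng = np.random.default_rng(8)
        a, b = rng.normal(0, 1, 15), rng.normal(0.5, 1, 12)
        res = anova_regulation(a, b)
        t = stats.ttest_ind(a, b, equal_var=True)
        assert res.F_stat == pytest.approx(t.statistic**2, abs=1e-10)
        assert res.p_value == pytest.approx(t.pvalue, abs=1e-12)


class TestFdr:
    def bh_from_definition(self, p):
        """Step-up adjustment computed straight from the definition."""
        p = np.asarray(p, dtype=float)
        m = len(p)
        order = np.argsort(p, kind="stable")
        adjusted = np.empty(m)
        running = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            running = min(running, p[i] * m / rank)
            adjusted[i] = running
        return adjusted

    def test_single_value_unchanged(self):
        assert fdr_adjust([0.03])[0] == pytest.approx(0.03)

    def test_equal_values_unchanged(self):
        np.testing.assert_allclose(fdr_adjust([0.2] * 4), [0.2] * 4)

    def test_matches_definition_oracle(self):
        rng = np.random.default_rng(9)
        p = rng.uniform(size=5)
        np.testing.assert_allclose(fdr_adjust(p), self.bh_from_definition(p), atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.5, 1.2])


class TestCoxTable:
    def test_table_layout_and_regulation(self):
        rng = np.random.default_rng(10)
        n = 80
        x1, records = simulate_survival(SurvivalSimDesign(n=n, beta_true=0.8, seed=11))
        expr = np.vstack([x1, rng.normal(size=n)])
        tumor = np.zeros(n, dtype=bool)
        tumor[: n // 2] = True
        expr[0, tumor] += 3.0
        times = [r.time for r in records]
        events = [r.event for r in records]
        df = cox_table(expr, ["mirA", "mirB"], times, events, tumor_mask=tumor)
        assert list(df["feature"]) == ["mirA", "mirB"]
        assert set(df.columns) >= {"beta", "hazard_ratio", "se", "p", "fdr", "direction"}
        assert df.loc[0, "direction"] == "up"
        np.testing.assert_allclose(df["hazard_ratio"], np.exp(df["beta"]), atol=1e-12)
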