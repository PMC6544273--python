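"""Cox fitting, model selection, concordance, KM/log-rank and IPCW Brier."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mfsurv.survival import (
    SurvivalData,
    backward_eliminate_aic,
    brier_ipcw,
    compare_models,
    encode_clinical,
    fit_cox,
    harrell_c,
    ibs_time_grid,
    integrated_brier,
    km_estimate,
    log_rank,
    stratified_split,
    univariate_screen,
    zscore_by_train,
)


def ph_frame(n, betas, seed=0, censoring=0.2, baseline_rate=0.01):
    """Multi-covariate PH data: standard-normal covariates, exponential baseline."""
    gen = np.random.default_rng(seed)
    X = pd.DataFrame({k: gen.standard_normal(n) for k in betas})
    eta = sum(b * X[k].to_numpy() for k, b in betas.items())
    t = gen.exponential(1.0, n) / (baseline_rate * np.exp(eta))
    if censoring > 0:
        r = baseline_rate * censoring / (1.0 - censoring)
        c = gen.exponential(1.0 / r, n)
    else:
        c = np.full(n, np.inf)
    return X, np.minimum(t, c), (t <= c).astype(int)


class TestFitCox:
    def test_recovers_known_binary_effect(self, ph_simulator):
        X, time, event = ph_simulator(n=2000, beta=0.7, censoring=0.2, seed=11)
        fit = fit_cox(X, time, event)
        assert abs(fit.summary.loc["x", "coef"] - 0.7) <= 0.1
        assert fit.summary.loc["x", "hr_lower"] < np.exp(0.7) < fit.summary.loc["x", "hr_upper"]
        assert fit.lrt_p < 1e-6

    def test_null_covariate_gives_hr_near_one(self, ph_simulator):
        X, time, event = ph_simulator(n=1500, beta=0.0, censoring=0.2, seed=5)
        fit = fit_cox(X, time, event)
        assert 0.8 < fit.summary.loc["x", "hr"] < 1.25

    def test_null_lrt_p_values_are_roughly_uniform(self, ph_simulator):
        ps = []
        for rep in range(80):
            X, time, event = ph_simulator(n=60, beta=0.0, censoring=0.2, seed=1000 + rep)
            ps.append(fit_cox(X, time, event).lrt_p)
        assert stats.kstest(ps, "uniform").pvalue > 1e-3

    def test_requires_events_and_complete_data(self):
        X = pd.DataFrame({"x": [0.0, 1.0, 2.0]})
        with pytest.raises(ValueError, match="event"):
            fit_cox(X, [1, 2, 3], [0, 0, 0])
        with pytest.raises(ValueError, match="missing"):
            fit_cox(pd.DataFrame({"x": [1.0, np.nan]}), [1, 2], [1, 1])

    def test_aic_and_lrt_are_consistent(self, ph_simulator):
        X, time, event = ph_simulator(n=400, beta=0.5, seed=2)
        fit = fit_cox(X, time, event)
        assert np.isclose(fit.aic, -2 * fit.log_likelihood + 2)
        assert fit.lrt_statistic >= 0


class TestUnivariateScreen:
    def test_only_signal_covariate_is_significant(self):
        X, time, event = ph_frame(400, {"signal": 0.8, "noise1": 0.0, "noise2": 0.0}, seed=3)
        table = univariate_screen(X, time, event)
        assert table.loc["signal", "p"] < 0.05
        assert table.loc["signal", "p"] == table["p"].min()
        assert set(table.columns) == {"coef", "se", "hr", "hr_lower", "hr_upper", "p"}

    def test_constant_covariate_rejected(self):
        X = pd.DataFrame({"c": np.ones(50)})
        gen = np.random.default_rng(0)
        with pytest.raises(ValueError, match="constant"):
            univariate_screen(X, gen.exponential(1, 50), np.ones(50, int))


class TestBackwardElimination:
    def test_signal_covariates_survive_elimination(self):
        X, time, event = ph_frame(
            500, {"s1": 0.8, "s2": 0.6, "n1": 0.0, "n2": 0.0, "n3": 0.0}, seed=7
        )
        selected, fit = backward_eliminate_aic(X, time, event)
        assert {"s1", "s2"} <= set(selected)
        full = fit_cox(X, time, event)
        assert fit.aic <= full.aic

    def test_single_strong_covariate_retained(self, ph_simulator):
        X, time, event = ph_simulator(n=500, beta=1.0, seed=9)
        selected, fit = backward_eliminate_aic(X, time, event)
        assert selected == ["x"] and fit is not None

    def test_pure_noise_shrinks_the_model(self):
        X, time, event = ph_frame(
            800, {f"n{i}": 0.0 for i in range(6)}, seed=13
        )
        selected, fit = backward_eliminate_aic(X, time, event)
        assert len(selected) < 6
        if fit is not None:
            assert fit.aic <= fit_cox(X, time, event).aic


class TestConcordance:
    def test_perfect_ordering(self):
        time = np.array([5.0, 3.0, 9.0, 1.0])
        event = np.ones(4, int)
        res = harrell_c(-time, time, event)  # risk = reversed survival time
        assert res.c_index == 1.0
        assert res.n_pairs == 6

    def test_single_pair_by_hand(self):
        res = harrell_c([3.0, 1.0], [2.0, 5.0], [1, 1])
        assert res.c_index == 1.0 and res.n_pairs == 1

    def test_random_scores_near_half(self, rng):
        n = 3000
        time = rng.exponential(100, n)
        event = (rng.random(n) < 0.8).astype(int)
        res = harrell_c(rng.standard_normal(n), time, event)
        assert abs(res.c_index - 0.5) < 0.05

    def test_negation_reverses_concordance(self, rng):
        n = 200
        time = rng.exponential(50, n)
        event = np.ones(n, int)
        scores = rng.standard_normal(n)
        c = harrell_c(scores, time, event).c_index
        c_neg = harrell_c(-scores, time, event).c_index
        assert np.isclose(c + c_neg, 1.0)


class TestKMLogRank:
    def test_km_without_censoring_is_empirical_survival(self):
        est = km_estimate([1.0, 2.0, 3.0], [1, 1, 1])
        assert np.allclose(est.at([1.0, 2.0, 3.0]), [2 / 3, 1 / 3, 0.0])

    def test_identical_groups_give_null_logrank(self):
        t = np.array([2.0, 4.0, 6.0, 8.0])
        e = np.array([1, 1, 0, 1])
        stat, p = log_rank(t, e, t, e)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hazard_ratio_two_is_detected(self, rng):
        a = rng.exponential(100, 500)
        b = rng.exponential(50, 500)
        _, p = log_rank(a, np.ones(500, int), b, np.ones(500, int))
        assert p < 0.05

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([], [])
        with pytest.raises(ValueError):
            log_rank([], [], [1.0], [1])


def _no_censoring_data(times):
    times = np.asarray(times, dtype=float)
    X = pd.DataFrame(index=range(len(times)))
    return SurvivalData(X, times, np.ones(len(times), int))


class TestBrier:
    def test_constant_half_prediction_scores_quarter(self):
        data = _no_censoring_data(np.arange(1.0, 21.0))
        times = np.array([5.0, 10.0, 15.0])
        est = np.full((20, 3), 0.5)
        assert np.allclose(brier_ipcw(est, data, data, times), 0.25)

    def test_perfect_predictor_scores_zero(self):
        data = _no_censoring_data(np.arange(1.0, 21.0))
        times = np.array([5.5, 10.5])
        est = (data.time[:, None] > times[None, :]).astype(float)
        assert np.allclose(brier_ipcw(est, data, data, times), 0.0)

    def test_time_beyond_followup_rejected(self):
        data = _no_censoring_data(np.arange(1.0, 11.0))
        with pytest.raises(ValueError):
            brier_ipcw(np.full((10, 1), 0.5), data, data, np.array([99.0]))

    def test_informative_model_beats_km_reference(self):
        X, time, event = ph_frame(600, {"x": 1.2}, seed=21, censoring=0.15)
        df = X.assign(os_days=time, event=event)
        train_df, test_df = stratified_split(df, ratio=0.7, seed=3)
        train = SurvivalData.from_frame(train_df)
        test = SurvivalData.from_frame(test_df)
        fit = fit_cox(train.X, train.time, train.event)
        grid = ibs_time_grid(train, test)
        assert integrated_brier(fit, train, test, grid) < integrated_brier(
            None, train, test, grid
        )

    def test_reference_ibs_in_uninformative_band(self):
        X, time, event = ph_frame(400, {"x": 0.0}, seed=30, censoring=0.2)
        df = X.assign(os_days=time, event=event)
        train_df, test_df = stratified_split(df, ratio=0.7, seed=1)
        train, test = SurvivalData.from_frame(train_df), SurvivalData.from_frame(test_df)
        grid = ibs_time_grid(train, test)
        ibs = integrated_brier(None, train, test, grid)
        assert 0.0 <= ibs <= 0.25


class TestStratifiedSplit:
    @staticmethod
    def cohort(n=113, n_events=94, seed=0):
        gen = np.random.default_rng(seed)
        event = np.zeros(n, int)
        event[:n_events] = 1
        gen.shuffle(event)
        return pd.DataFrame({"os_days": gen.exponential(400, n), "event": event})

    def test_seven_three_split_sizes(self):
        train, test = stratified_split(self.cohort(), ratio=0.7, seed=4)
        assert (len(train), len(test)) == (80, 33)

    def test_determinism_under_seed(self):
        df = self.cohort()
        a = stratified_split(df, seed=9)
        b = stratified_split(df, seed=9)
        assert a[0].index.equals(b[0].index) and a[1].index.equals(b[1].index)
        c = stratified_split(df, seed=10)
        assert not a[1].index.equals(c[1].index)

    def test_event_fractions_balanced(self):
        df = self.cohort()
        train, test = stratified_split(df, ratio=0.7, seed=2)
        # allocation is exact up to one subject per stratum
        assert abs(train["event"].mean() - test["event"].mean()) <= 1 / len(test)

    def test_tiny_stratum_rejected(self):
        df = pd.DataFrame({"os_days": [1.0, 2.0, 3.0], "event": [1, 1, 0]})
        with pytest.raises(ValueError, match="stratify|split"):
            stratified_split(df, ratio=0.7, seed=0)


class TestCompareModels:
    def test_single_model_report_structure(self):
        X, time, event = ph_frame(300, {"x": 0.8, "z": 0.0}, seed=17)
        df = X.assign(os_days=time, event=event)
        train_df, test_df = stratified_split(df, ratio=0.7, seed=5)
        train, test = SurvivalData.from_frame(train_df), SurvivalData.from_frame(test_df)
        report = compare_models(train, test, {"only": ["x"]})
        assert set(report["models"]) == {"only"}
        entry = report["models"]["only"]
        assert 0.5 < entry["c_index"] <= 1.0
        assert 0.0 <= entry["ibs"] <= 1.0
        assert "ibs" in report["reference"]


def test_encode_clinical_reference_levels():
    df = pd.DataFrame(
        {
            "age": [60, 50],
            "sex": ["male", "female"],
            "mgmt": ["methylated", "unmethylated"],
            "resection": ["non-total", "total"],
        }
    )
    enc = encode_clinical(df)
    assert enc.iloc[0].tolist() == [60.0, 1.0, 1.0, 1.0]
    assert enc.iloc[1].tolist() == [50.0, 0.0, 0.0, 0.0]


def test_zscore_by_train_uses_training_statistics():
    train = pd.DataFrame({"f": [0.0, 2.0, 4.0]})
    test = pd.DataFrame({"f": [2.0, 6.0]})
    tr, te = zscore_by_train(train, test, ["f"])
    assert np.allclose(tr["f"], [-np.sqrt(1.5), 0, np.sqrt(1.5)])
    assert te["f"].iloc[0] == 0.0  # train mean maps to zero
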