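"""Hazard fitting, survival composition, and likelihood oracles."""

import warnings

import numpy as np
import pandas as pd
import pytest

from dtsurv import (DiscreteTimeHazardModel, IntervalGrid, PersonPeriodTable,
                    SimulationConfig, SklearnClassifier, SurvivalCurves,
                    expand_train, fit_classifier_model, fit_link_model,
                    make_quantile_grid, simulate, threshold_effect)
from conftest import make_data


class ConstantClassifier:
    """Degenerate contract implementation: the same probability everywhere."""

    def __init__(self, p: float):
        self.p = p
        self.fitted_ = self

    def fit(self, X, y):
        return self

    def predict_probability(self, X):
        return np.full(len(X), self.p)


class RandomClassifier:
    """Adversarial contract implementation: arbitrary valid probabilities."""

    def __init__(self, seed: int):
        self.seed = seed
        self.fitted_ = self

    def fit(self, X, y):
        return self

    def predict_probability(self, X):
        return np.random.default_rng(self.seed).uniform(0, 1, len(X))


def make_table(grid, intervals, d, x=None) -> PersonPeriodTable:
    """Hand-built person-period table (one independent subject per row)."""
    intervals = np.asarray(intervals)
    df = pd.DataFrame({
        "subject_id": np.arange(intervals.shape[0]),
        "interval": intervals,
        "interval_label": pd.Categorical.from_codes(intervals - 1,
                                                    categories=grid.labels()),
        "t_lo": grid.lower[intervals - 1],
        "t_hi": grid.upper[intervals - 1],
    })
    names = []
    if x is not None:
        df["x1"] = np.asarray(x, dtype=float)
        names = ["x1"]
    df["d"] = np.asarray(d)
    return PersonPeriodTable(table=df, grid=grid, covariate_names=names)


class TestLinkModel:
    def test_saturated_model_reproduces_life_table(self, unit_grid, rng):
        # with interval dummies only, predicted hazards equal the empirical
        # conditional failure proportions k_j / n_j
        n = 300
        data = make_data(rng.uniform(0.01, 6.0, n), rng.integers(0, 2, n),
                         covariates=np.empty((n, 0)))
        table = expand_train(data, unit_grid, "observed_any")
        res = fit_link_model(table, "logit")
        lam = res.predict_hazards(pd.DataFrame(index=[0]))[0]
        tab = table.table
        for j in range(1, 6):
            rows = tab[tab["interval"] == j]
            np.testing.assert_allclose(lam[j - 1],
                                       rows["d"].mean(), atol=1e-6)
        # hence S(t_j) matches the life-table survival product
        surv = SurvivalCurves(unit_grid, lam).survival[0]
        life = np.cumprod([1 - tab[tab["interval"] == j]["d"].mean()
                           for j in range(1, 6)])
        np.testing.assert_allclose(surv, life, atol=1e-5)

    def test_binary_covariate_equals_2x2_log_odds_ratio(self):
        # identical per-interval 2x2 tables: the pooled conditional log
        # odds ratio is the single-table value log(ad/bc)
        grid = IntervalGrid([0.0, 1.0, 2.0])
        a, b, c, d_ = 30, 70, 10, 90  # x=1: a/b events/survivors; x=0: c/d
        rows_per_int = ([1] * (a + b) + [0] * (c + d_))
        dvals = ([1] * a + [0] * b + [1] * c + [0] * d_)
        intervals = np.repeat([1, 2], len(rows_per_int))
        x = np.tile(rows_per_int, 2)
        dcol = np.tile(dvals, 2)
        table = make_table(grid, intervals, dcol, x)
        res = fit_link_model(table, "logit")
        expected = np.log(a * d_ / (b * c))
        np.testing.assert_allclose(res.beta["x1"], expected, atol=1e-6)
        # both interval intercepts equal the x=0 empirical logit
        np.testing.assert_allclose(res.alpha.to_numpy(),
                                   np.log(c / d_), atol=1e-6)

    def test_cloglog_recovers_proportional_hazards_coefficient(self):
        # grouped-PH link on fine grid: beta estimates the Cox log HR
        sim = simulate(SimulationConfig(
            n=2000, n_normal=1, n_binary=0, beta=(0.7,),
            family="weibull_ph", censoring_rate=0.2, seed=7))
        horizon = float(np.quantile(sim.data.time, 0.9))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            res = DiscreteTimeHazardModel(sim.data, horizon, n_intervals=25,
                                          link="cloglog").fit()
        assert abs(res.beta["x1"] - 0.7) < 0.1

    def test_logit_close_to_cloglog_for_small_hazards(self):
        # rare events per interval: odds ~ probability, so the two links
        # give nearly identical hazards
        sim = simulate(SimulationConfig(n=3000, n_normal=1, n_binary=0,
                                        beta=(0.4,), family="exponential",
                                        rate=0.02, censoring_rate=0.0,
                                        seed=3))
        horizon = float(np.quantile(sim.data.time, 0.10))
        model = dict(horizon=horizon, n_intervals=10)
        r1 = DiscreteTimeHazardModel(sim.data, link="logit", **model).fit()
        r2 = DiscreteTimeHazardModel(sim.data, link="cloglog", **model).fit()
        X = sim.data.covariates.head(50)
        h1, h2 = r1.predict_hazards(X), r2.predict_hazards(X)
        assert h1.max() < 0.05
        assert np.max(np.abs(h1 - h2) / h2) < 0.10

    def test_empty_interval_raises_instructive_error(self):
        grid = IntervalGrid([0.0, 1.0, 2.0, 3.0])
        data = make_data([0.5, 1.5, 1.8], [1, 1, 0])
        table = expand_train(data, grid, "observed_any")
        with pytest.raises(ValueError, match="fewer intervals"):
            fit_link_model(table)

    def test_perfect_separation_raises(self):
        grid = IntervalGrid([0.0, 1.0])
        table = make_table(grid, [1] * 40, [1] * 20 + [0] * 20,
                           [1.0] * 20 + [0.0] * 20)
        with pytest.raises((RuntimeError, ValueError)):
            fit_link_model(table)

    def test_unknown_link_rejected(self, unit_grid):
        data = make_data([2.5], [1])
        table = expand_train(data, unit_grid, "observed_any")
        with pytest.raises(ValueError, match="unknown link"):
            fit_link_model(table, "cauchy")


class TestClassifierModel:
    def test_constant_half_classifier_gives_quarter_survival(self, unit_grid):
        data = make_data([2.5, 1.5, 4.5], [1, 1, 0])
        table = expand_train(data, unit_grid, "observed_any")
        res = fit_classifier_model(table, ConstantClassifier(0.5))
        lam = res.predict_hazards(data.covariates.head(1))
        np.testing.assert_allclose(lam, 0.5)
        S = res.predict_survival(data.covariates.head(1), eval_times=[2.0])
        np.testing.assert_allclose(S, 0.25)

    def test_logistic_classifier_agrees_with_link_model(self, unit_grid, rng):
        from sklearn.linear_model import LogisticRegression

        n = 400
        data = make_data(rng.uniform(0.01, 6.0, n), rng.integers(0, 2, n),
                         n_cov=2, seed=11)
        table = expand_train(data, unit_grid, "observed_any")
        res_glm = fit_link_model(table, "logit")
        clf = SklearnClassifier(LogisticRegression(penalty=None,
                                                   max_iter=2000, tol=1e-10))
        res_clf = fit_classifier_model(table, clf)
        X = data.covariates.head(30)
        np.testing.assert_allclose(res_clf.predict_hazards(X),
                                   res_glm.predict_hazards(X), atol=2e-4)

    def test_forest_beats_linear_logit_on_threshold_effect(self):
        # a symmetric threshold effect is invisible to a linear logit model
        from sklearn.ensemble import RandomForestClassifier

        sim = simulate(SimulationConfig(
            n=1500, n_normal=2, n_binary=0, beta=(0.0, 0.0),
            nonlinear=threshold_effect(column=0, threshold=0.8, effect=2.0),
            family="weibull_ph", censoring_rate=0.3, seed=5))
        horizon = float(np.quantile(sim.data.time, 0.8))
        train = sim.data.subset(np.arange(1000))
        test = sim.data.subset(np.arange(1000, 1500))
        eval_times = np.quantile(train.time, [0.2, 0.35, 0.5, 0.65])
        common = dict(horizon=horizon, n_intervals=8)
        res_lin = DiscreteTimeHazardModel(train, link="logit", **common).fit()
        clf = SklearnClassifier(RandomForestClassifier(
            n_estimators=150, min_samples_leaf=25, random_state=0))
        res_rf = DiscreteTimeHazardModel(train, link=None, classifier=clf,
                                         **common).fit()
        from dtsurv import PredictionMatrix, evaluate_predictions

        ibs = {}
        for name, res in [("linear", res_lin), ("forest", res_rf)]:
            pm = PredictionMatrix(
                res.predict_event_probability(test.covariates, eval_times),
                eval_times, model=name)
            ibs[name] = evaluate_predictions(pm, test).ibs
        assert ibs["forest"] < ibs["linear"]

    def test_contract_violation_detected(self, unit_grid):
        class BadClassifier(ConstantClassifier):
            def predict_probability(self, X):
                return np.full(len(X), 1.7)

        data = make_data([2.5, 3.5, 5.0], [1, 0, 0])
        table = expand_train(data, unit_grid, "observed_any")
        with pytest.raises(ValueError, match="probab"):
            fit_classifier_model(table, BadClassifier(0.5))

    def test_seeded_classifier_is_reproducible(self, unit_grid, rng):
        from sklearn.ensemble import RandomForestClassifier

        n = 200
        data = make_data(rng.uniform(0.01, 6.0, n), rng.integers(0, 2, n))
        table = expand_train(data, unit_grid, "observed_any")
        hz = []
        for _ in range(2):
            clf = SklearnClassifier(RandomForestClassifier(n_estimators=30),
                                    seed=42)
            res = fit_classifier_model(table, clf)
            hz.append(res.predict_hazards(data.covariates.head(20)))
        np.testing.assert_array_equal(hz[0], hz[1])

    def test_adversarial_classifier_yields_valid_curves(self, unit_grid, rng):
        data = make_data(rng.uniform(0.01, 6.0, 50), rng.integers(0, 2, 50))
        table = expand_train(data, unit_grid, "observed_any")
        for seed in range(5):
            res = fit_classifier_model(table, RandomClassifier(seed))
            curves = res.predict_survival(data.covariates.head(10))
            S = curves.survival
            assert np.all((S >= 0) & (S <= 1))
            assert np.all(np.diff(S, axis=1) <= 0)


class TestPrediction:
    def test_hazards_equal_classifier_output_on_expanded_rows(self, unit_grid):
        data = make_data([2.5, 5.0], [1, 0], n_cov=2, seed=9)
        table = expand_train(data, unit_grid, "observed_any")
        res = fit_classifier_model(table, RandomClassifier(3))
        X = data.covariates
        lam = res.predict_hazards(X)
        # direct recomputation through the prediction expansion
        from dtsurv import expand_for_prediction
        from dtsurv.hazard import _features

        pp = expand_for_prediction(X, unit_grid)
        direct = res.classifier.predict_probability(
            _features(pp, res.covariate_names, res.scaler, res.encoding, 5))
        np.testing.assert_allclose(lam.ravel(),
                                   np.clip(direct, 1e-6, 1 - 1e-6))

    def test_subject_permutation_equivariance(self, unit_grid, rng):
        data = make_data(rng.uniform(0.01, 6.0, 60), rng.integers(0, 2, 60),
                         n_cov=2, seed=2)
        table = expand_train(data, unit_grid, "observed_any")
        res = fit_link_model(table, "logit")
        X = data.covariates.head(20)
        perm = rng.permutation(20)
        np.testing.assert_allclose(res.predict_hazards(X)[perm],
                                   res.predict_hazards(X.iloc[perm]))

    def test_schema_mismatch_rejected(self, unit_grid, rng):
        data = make_data(rng.uniform(0.01, 6.0, 60), rng.integers(0, 2, 60),
                         n_cov=2, seed=1)
        res = fit_link_model(expand_train(data, unit_grid, "observed_any"))
        with pytest.raises(ValueError, match="missing"):
            res.predict_hazards(pd.DataFrame({"x1": [0.0]}))


class TestSurvivalCurves:
    def test_product_rule_and_step_behaviour(self, unit_grid):
        curves = SurvivalCurves(unit_grid, np.full((1, 5), 0.5))
        S = curves.evaluate([1.0, 2.0, 2.9])
        np.testing.assert_allclose(S[0], [0.5, 0.25, 0.25])

    def test_zero_hazard_gives_unit_survival(self, unit_grid):
        curves = SurvivalCurves(unit_grid, np.zeros((1, 5)))
        np.testing.assert_array_equal(curves.evaluate([0.0, 2.5, 5.0]), 1.0)

    def test_matches_log_space_oracle(self, unit_grid, rng):
        lam = rng.uniform(0.01, 0.9, (10, 5))
        curves = SurvivalCurves(unit_grid, lam)
        t = rng.uniform(0, 5, 20)
        expected = np.empty((10, 20))
        for k, tk in enumerate(t):
            mask = unit_grid.upper <= tk
            expected[:, k] = np.exp(np.sum(np.log1p(-lam[:, mask]), axis=1))
        np.testing.assert_allclose(curves.evaluate(t), expected, atol=1e-12)

    def test_extrapolation_refused(self, unit_grid):
        curves = SurvivalCurves(unit_grid, np.full((1, 5), 0.1))
        with pytest.raises(ValueError, match="horizon"):
            curves.evaluate([5.5])


class TestLogLikelihood:
    def test_single_event_row(self):
        grid = IntervalGrid([0.0, 1.0])
        table = make_table(grid, [1], [1])
        res = fit_classifier_model(table, ConstantClassifier(0.3),
                                   standardize=False)
        np.testing.assert_allclose(res.log_likelihood(table), np.log(0.3))

    def test_row_sum_equals_subject_level_product(self, unit_grid, rng):
        # Per-subject likelihood (product of hazard^d (1-hazard)^(1-d) over
        # the subject's intervals) must equal the row-level binomial sum.
        n = 120
        data = make_data(rng.uniform(0.01, 6.0, n), rng.integers(0, 2, n),
                         n_cov=2, seed=21)
        table = expand_train(data, unit_grid, "observed_any")
        res = fit_link_model(table, "logit")
        row_ll = res.log_likelihood(table)
        censored = data.administratively_censor(5.0)
        lam_all = res.predict_hazards(censored.covariates)
        subject_ll = 0.0
        for i in range(n):
            j_i = unit_grid.index(censored.time[i]) if censored.time[i] > 0 else 0
            for j in range(1, j_i + 1):
                d_ij = int(censored.event[i] == 1 and j == j_i)
                lam = lam_all[i, j - 1]
                subject_ll += d_ij * np.log(lam) + (1 - d_ij) * np.log(1 - lam)
        np.testing.assert_allclose(row_ll, subject_ll, rtol=1e-12)

    def test_doubling_subjects_doubles_loglik(self, unit_grid, rng):
        data = make_data(rng.uniform(0.01, 6.0, 50), rng.integers(0, 2, 50))
        table = expand_train(data, unit_grid, "observed_any")
        res = fit_link_model(table, "logit")
        doubled = PersonPeriodTable(
            table=pd.concat([table.table, table.table], ignore_index=True),
            grid=unit_grid, covariate_names=table.covariate_names)
        np.testing.assert_allclose(res.log_likelihood(doubled),
                                   2 * res.log_likelihood(table), rtol=1e-12)


class TestModelClass:
    def test_from_dataframe_and_summary(self, rng):
        n = 200
        df = pd.DataFrame({
            "time": rng.exponential(3, n), "event": rng.integers(0, 2, n),
            "age": rng.normal(60, 10, n),
        })
        model = DiscreteTimeHazardModel.from_dataframe(
            df, horizon=4.0, n_intervals=4, link="cloglog")
        res = model.fit()
        text = res.summary()
        assert "cloglog" in text and "age" in text
        assert res.params.shape == (5,) and np.all(np.isfinite(res.bse))

    def test_save_load_roundtrip(self, unit_grid, rng, tmp_path):
        data = make_data(rng.uniform(0.01, 6.0, 80), rng.integers(0, 2, 80))
        res = fit_link_model(expand_train(data, unit_grid, "observed_any"))
        path = tmp_path / "model.pkl"
        res.save(path)
        from dtsurv import DiscreteTimeHazardResults
        back = DiscreteTimeHazardResults.load(path)
        X = data.covariates.head(5)
        np.testing.assert_array_equal(back.predict_hazards(X),
                                      res.predict_hazards(X))

    def test_requires_exactly_one_predictor_kind(self, rng):
        data = make_data(rng.uniform(0.01, 6.0, 30), np.ones(30, dtype=int))
        with pytest.raises(ValueError, match="exactly one"):
            DiscreteTimeHazardModel(data, 5.0, n_intervals=3, link=None)
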