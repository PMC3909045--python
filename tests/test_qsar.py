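import warnings

import numpy as np
import pandas as pd
import pytest

import inktqsar as iq
from oracles import ols_predictions


def frame(arr):
    arr = np.asarray(arr, dtype=float)
    return pd.DataFrame(arr, index=[f"C{i}" for i in range(arr.shape[0])],
                        columns=[f"x{j}" for j in range(arr.shape[1])])


@pytest.fixture()
def planted_signal(rng):
    """y = 2*x3 + tiny noise among 10 nuisance descriptors."""
    X = frame(rng.normal(size=(100, 11)))
    y = 2.0 * X["x3"] + rng.normal(0, 0.01, size=100)
    return X, y


class TestStepwiseMLR:
    def test_recovers_single_planted_descriptor(self, planted_signal):
        X, y = planted_signal
        model = iq.stepwise_mlr_fit(X, y)
        assert model.selected == ["x3"]
        # stored per-scaled-unit; back out the raw-scale slope
        slope = model.coefficients["x3"] / model.x_std["x3"]
        assert slope == pytest.approx(2.0, abs=0.02)
        assert model.r2 > 0.999

    def test_pure_noise_rarely_admits_anything(self):
        empty = 0
        for seed in range(100):
            r = np.random.default_rng(seed)
            X = frame(r.normal(size=(100, 10)))
            y = pd.Series(r.normal(size=100), index=X.index)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = iq.stepwise_mlr_fit(X, y)
            empty += not model.selected
        assert empty >= 95

    def test_duplicated_column_never_coselected(self, planted_signal):
        X, y = planted_signal
        X = X.copy()
        X["x3_dup"] = X["x3"]
        model = iq.stepwise_mlr_fit(X, y)
        assert not {"x3", "x3_dup"} <= set(model.selected)

    def test_backward_step_removes_obsolete_descriptor(self, rng):
        # x0 is a noisy proxy for x1 + x2: it enters first (best marginal
        # fit) but becomes redundant once both true descriptors are in
        x1 = rng.normal(size=300)
        x2 = rng.normal(size=300)
        x0 = (x1 + x2) / np.sqrt(2) + rng.normal(0, 0.4, 300)
        X = frame(np.column_stack([x0, x1, x2]))
        y = pd.Series(x1 + x2 + rng.normal(0, 0.05, 300), index=X.index)
        model = iq.stepwise_mlr_fit(X, y)
        assert model.trace[0]["descriptor"] == "x0"
        assert any(t["action"] == "remove" and t["descriptor"] == "x0"
                   for t in model.trace)
        assert set(model.selected) == {"x1", "x2"}

    def test_thresholds_must_be_ordered(self, planted_signal):
        X, y = planted_signal
        with pytest.raises(ValueError):
            iq.stepwise_mlr_fit(X, y, p_enter=0.2, p_remove=0.1)

    def test_prediction_consistency_and_missing_column(self, planted_signal):
        X, y = planted_signal
        model = iq.stepwise_mlr_fit(X, y)
        fitted = model.predict(X)
        assert np.corrcoef(fitted, y)[0, 1] > 0.999
        with pytest.raises(KeyError, match="x3"):
            model.predict(X.drop(columns=["x3"]))


class TestPLS:
    def test_exact_linear_relation_is_fit_perfectly(self, rng):
        # single descriptor carrying y exactly: one component suffices
        X = frame(rng.normal(size=(30, 1)))
        y = 3.0 * X["x0"]
        model = iq.pls_fit(X, y, n_components=1)
        assert model.r2 == pytest.approx(1.0, abs=1e-8)

    def test_full_components_reproduce_ols(self, rng):
        X = frame(rng.normal(size=(25, 4)))
        y = pd.Series(rng.normal(size=25), index=X.index)
        model = iq.pls_fit(X, y, n_components=4)
        expected = ols_predictions(X.to_numpy(), y.to_numpy())
        assert np.max(np.abs(model.predict(X).to_numpy() - expected)) < 1e-6

    def test_row_permutation_leaves_coefficients_unchanged(self, rng):
        X = frame(rng.normal(size=(20, 5)))
        y = pd.Series(rng.normal(size=20), index=X.index)
        perm = rng.permutation(20)
        a = iq.pls_fit(X, y, 2)
        b = iq.pls_fit(X.iloc[perm], y.iloc[perm], 2)
        pd.testing.assert_series_equal(a.coefficients, b.coefficients,
                                       atol=1e-10, rtol=0)

    def test_score_vectors_orthogonal(self, rng):
        X = frame(rng.normal(size=(30, 6)))
        y = pd.Series(rng.normal(size=30), index=X.index)
        T = iq.pls_fit(X, y, 3).x_scores
        gram = T.T @ T
        assert np.all(np.abs(gram - np.diag(np.diag(gram))) < 1e-8)

    def test_constant_response_rejected(self, rng):
        X = frame(rng.normal(size=(15, 3)))
        with pytest.raises(ValueError, match="variance"):
            iq.pls_fit(X, pd.Series(1.0, index=X.index), 1)


class TestCrossValidation:
    def test_noiseless_model_has_unit_q2(self, rng):
        X = frame(rng.normal(size=(50, 4)))
        y = X["x1"] * 2.0 - X["x3"]
        q2, press = iq.kfold_q2(X, y, lambda a, b: iq.pls_fit(a, b, 4), k=7,
                                seed=0)
        assert q2 == pytest.approx(1.0, abs=1e-6)
        assert len(press) == 7

    def test_intercept_only_model_has_zero_q2(self, rng):
        class MeanModel:
            def __init__(self, mean):
                self.mean = mean

            def predict(self, X):
                return pd.Series(self.mean, index=X.index)

        X = frame(rng.normal(size=(200, 3)))
        y = pd.Series(rng.normal(size=200), index=X.index)
        q2, _ = iq.kfold_q2(X, y, lambda a, b: MeanModel(b.mean()), k=7, seed=0)
        assert abs(q2) < 0.1

    def test_permuted_response_has_no_predictivity(self, rng):
        config = iq.recovery_benchmark_config(seed=12)
        desc, rec, _ = iq.generate_dataset(config)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mat = iq.aggregate_replicates(iq.normalize_to_reference(
                iq.read_response_table(rec), "CPD-001"), "CPD-001")
        y = np.log(mat.cell("mice/in-vivo", "IFN-γ").dropna())
        X = desc.reindex(y.index)
        y_perm = pd.Series(rng.permutation(y.to_numpy()), index=y.index)
        q2, _ = iq.kfold_q2(X, y_perm, lambda a, b: iq.pls_fit(a, b, 2), k=7,
                            seed=0)
        assert q2 <= 0.1

    def test_q2_never_exceeds_r2(self, rng):
        for _ in range(50):
            n, p = 40, 6
            X = frame(rng.normal(size=(n, p)))
            beta = rng.normal(size=p)
            y = pd.Series(X.to_numpy() @ beta + rng.normal(0, 1.0, n),
                          index=X.index)
            model = iq.pls_fit(X, y, 3)
            q2, _ = iq.kfold_q2(X, y, lambda a, b: iq.pls_fit(a, b, 3), k=7,
                                seed=1)
            assert q2 <= model.r2 + 1e-10

    def test_component_choice_stops_on_small_gains(self, rng):
        X = frame(rng.normal(size=(60, 8)))
        y = X["x0"] + 0.5 * X["x1"] + rng.normal(0, 0.2, 60)
        best, q2s = iq.choose_pls_components(X, y, max_components=6, seed=0)
        assert 1 <= best <= len(q2s)
        assert max(q2s) - q2s[best - 1] < 0.01 + 1e-12


class TestPredictionQuality:
    def test_rank_correlation_on_held_out_compounds(self):
        # generator calibrated for R^2 ~ 0.8; 100 train / 50 test split
        config = iq.recovery_benchmark_config(seed=21)
        desc, rec, truth = iq.generate_dataset(config)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mat = iq.aggregate_replicates(iq.normalize_to_reference(
                iq.read_response_table(rec), "CPD-001"), "CPD-001")
        y = np.log(mat.cell("mice/in-vivo", "IFN-γ").dropna())
        X = desc.reindex(y.index)
        train, test = y.index[:100], y.index[100:]
        model = iq.stepwise_mlr_fit(X.loc[train], y.loc[train])
        pred = iq.predict_desirability(model, X.loc[test])
        beta = truth.coefficients[("mice/in-vivo", "IFN-γ")]
        true_signal = pd.Series(desc.loc[test].to_numpy() @ beta, index=test)
        rho, _ = iq.spearman_correlation(pred, true_signal)
        assert rho >= 0.7
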