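"""Multinomial classification: softmax path, tuning, calculator export."""

import numpy as np
import pytest
from scipy.optimize import minimize

from phenoclust import classify
from phenoclust.classify import (
    ClassifierModel,
    classify_cohort,
    export_calculator,
    fold_scaling,
    import_calculator,
    calculator_probabilities,
    linear_predictors,
    softmax_probabilities,
    train_classifier,
)
from phenoclust.preprocess import VARIABLE_SETS, FeatureMatrix, mad_scale


def toy_model(coef, var_names=("x1", "x2"), classes=("C1", "C2")):
    coef = np.asarray(coef, dtype=float)
    p = coef.shape[0] - 1
    return ClassifierModel(
        classes=classes, coef=coef, var_names=var_names[:p],
        center=np.zeros(p), scale=np.ones(p),
        alpha=0.5, lam=0.01, variant="A",
    )


def make_fm(X, var_names, scaled=True):
    X = np.asarray(X, dtype=float)
    fm = FeatureMatrix(values=X, mask=np.isfinite(X),
                       var_names=tuple(var_names),
                       subject_ids=tuple(f"s{i}" for i in range(X.shape[0])))
    return mad_scale(fm) if scaled else fm


class TestSoftmax:
    def test_uniform_for_equal_predictors(self):
        np.testing.assert_allclose(softmax_probabilities(np.zeros(4)), 0.25)

    def test_shift_invariance(self):
        f = np.array([0.3, -1.2, 2.5, 0.0])
        np.testing.assert_allclose(softmax_probabilities(f),
                                   softmax_probabilities(f + 123.4), atol=1e-12)

    def test_log_spaced_closed_form(self):
        f = np.log([1.0, 2.0, 3.0, 4.0])
        np.testing.assert_allclose(softmax_probabilities(f), [0.1, 0.2, 0.3, 0.4],
                                   atol=1e-12)

    def test_rows_sum_to_one_even_for_extreme_inputs(self):
        f = np.array([[1000.0, -1000.0, 0.0], [5e2, 5e2, 5e2]])
        probs = softmax_probabilities(f)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-12)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            softmax_probabilities(np.array([np.inf, 0.0]))


class TestLinearPredictors:
    def test_zero_coefficients_give_zero(self):
        model = toy_model(np.zeros((3, 2)))
        np.testing.assert_allclose(linear_predictors(model, np.array([1.0, 2.0])), 0.0)

    def test_intercept_only(self):
        model = toy_model(np.array([[1.0, 2.0]]), var_names=())
        np.testing.assert_allclose(linear_predictors(model, np.zeros(0)), [1.0, 2.0])

    def test_hand_computed_dot_product(self):
        coef = np.array([[0.5, -0.5], [2.0, 1.0], [-1.0, 3.0]])
        model = toy_model(coef)
        x = np.array([1.5, 2.0])
        f = linear_predictors(model, x)
        np.testing.assert_allclose(f, [0.5 + 3.0 - 2.0, -0.5 + 1.5 + 6.0])

    def test_missing_predictor_named_in_error(self):
        model = toy_model(np.zeros((3, 2)))
        with pytest.raises(KeyError, match="x2"):
            linear_predictors(model, {"x1": 1.0})


class TestTrainClassifier:
    def test_separable_toy_perfect_training_accuracy(self):
        rng = np.random.default_rng(0)
        names = VARIABLE_SETS["model_b"]
        X = rng.standard_normal((40, 7))
        X[:20, 0] += 8.0
        y = np.array(["C1"] * 20 + ["C2"] * 20)
        fm = make_fm(X, names)
        model = train_classifier(fm, y, variant="B", alpha_grid=(0.5,),
                                 lambda_grid=(1e-6, 1e-3), cv=5, seed=0)
        assert model.training_concordance == 1.0

    def test_huge_penalty_collapses_to_class_frequencies(self):
        rng = np.random.default_rng(1)
        names = VARIABLE_SETS["model_b"]
        X = rng.standard_normal((60, 7))
        y = np.array(["C1"] * 45 + ["C2"] * 15)
        fm = make_fm(X, names)
        model = train_classifier(fm, y, variant="B", alpha_grid=(0.0,),
                                 lambda_grid=(1e4,), cv=5, seed=0)
        assert np.abs(model.coef[1:]).max() < 1e-4
        res = classify_cohort(model, fm)
        np.testing.assert_allclose(res.probabilities[:, 0], 0.75, atol=0.02)
        # the sparse elastic-net path shrinks all slopes to zero as well
        sparse = train_classifier(fm, y, variant="B", alpha_grid=(0.5,),
                                  lambda_grid=(1e4,), cv=5, seed=0)
        assert np.abs(sparse.coef[1:]).max() < 1e-4

    def test_unpenalized_fit_matches_convex_oracle(self):
        """Near-zero penalty agrees with direct NLL minimization.

        Oracle: scipy.optimize on the multinomial negative log-likelihood
        (full parameterization, one coefficient block pinned to zero for
        identifiability); agreement is checked on predicted probabilities,
        which are invariant to the parameterization.
        """
        rng = np.random.default_rng(2)
        names = VARIABLE_SETS["model_b"][:3]
        n = 200
        X = rng.standard_normal((n, 3))
        true = np.array([[0.5, -0.5], [1.0, 0.0], [0.0, 1.0], [-1.0, 0.5]])
        f = np.column_stack([np.ones(n), X]) @ true
        probs = softmax_probabilities(np.column_stack([f, np.zeros(n)]))
        y = np.array([f"C{rng.choice(3, p=p) + 1}" for p in probs])
        fm = make_fm(X, names, scaled=False)
        fm = mad_scale(fm)
        model = train_classifier(fm, y, variant="B", variables=names,
                                 alpha_grid=(0.0,), lambda_grid=(1e-8,),
                                 cv=3, seed=0)

        # fm.values are already on the scaled predictor space the model uses
        Dz = np.column_stack([np.ones(n), fm.values])
        codes = np.array([int(c[1]) - 1 for c in y])

        def nll(theta):
            B = np.zeros((4, 3))
            B[:, :2] = theta.reshape(4, 2)
            F = Dz @ B
            F -= F.max(axis=1, keepdims=True)
            return -np.sum(F[np.arange(n), codes] - np.log(np.exp(F).sum(axis=1)))

        res = minimize(nll, np.zeros(8), method="BFGS",
                       options={"gtol": 1e-9, "maxiter": 2000})
        B = np.zeros((4, 3))
        B[:, :2] = res.x.reshape(4, 2)
        oracle_probs = softmax_probabilities(Dz @ B)
        fitted_probs = softmax_probabilities(Dz @ model.coef)
        np.testing.assert_allclose(fitted_probs, oracle_probs, atol=2e-3)

    def test_parameter_recovery_improves_with_n(self):
        """Coefficient error vs the generating model shrinks with n."""
        names = VARIABLE_SETS["model_b"]
        rng = np.random.default_rng(3)
        true = rng.normal(0, 1.0, (8, 4))
        true -= true.mean(axis=1, keepdims=True)

        def fit_error(n, seed):
            rng2 = np.random.default_rng(seed)
            X = rng2.standard_normal((n, 7))
            probs = softmax_probabilities(np.column_stack([np.ones(n), X]) @ true)
            y = np.array([f"C{rng2.choice(4, p=p) + 1}" for p in probs])
            fm = make_fm(X, names, scaled=False)
            fm.center = np.zeros(7)
            fm.scale = np.ones(7)
            model = train_classifier(fm, y, variant="B", alpha_grid=(0.0,),
                                     lambda_grid=(1e-8,), cv=3, seed=0)
            est = model.coef - model.coef.mean(axis=1, keepdims=True)
            return np.abs(est - true).mean()

        assert fit_error(5000, 10) < fit_error(500, 10)

    def test_small_class_rejected(self):
        names = VARIABLE_SETS["model_b"]
        X = np.random.default_rng(0).standard_normal((10, 7))
        y = np.array(["C1"] * 9 + ["C2"])
        with pytest.raises(ValueError, match="at least 2"):
            train_classifier(make_fm(X, names), y, variant="B",
                             alpha_grid=(0.5,), lambda_grid=(1e-2,), cv=2)

    def test_empty_grid_rejected(self, scaled_features, cluster_labels):
        with pytest.raises(ValueError, match="grid"):
            train_classifier(scaled_features, cluster_labels, variant="A",
                             alpha_grid=(), lambda_grid=(1e-2,))


class TestClassifyCohort:
    def test_self_classification_matches_training_concordance(
        self, model_a, scaled_features, cluster_labels
    ):
        from phenoclust.preprocess import apply_scaling
        # classify_cohort applies model scaling internally; feed raw values
        raw = FeatureMatrix(
            values=scaled_features.values * np.ones(1),  # already scaled copy
            mask=scaled_features.mask,
            var_names=scaled_features.var_names,
            subject_ids=scaled_features.subject_ids,
        )
        # reconstruct raw scale so the model's stored scaling applies cleanly
        raw.values = scaled_features.values * scaled_features.scale + scaled_features.center
        raw.values = np.where(scaled_features.mask, raw.values, np.nan)
        res = classify_cohort(model_a, raw, reference=cluster_labels)
        assert res.concordance == pytest.approx(model_a.training_concordance)

    def test_probability_rows_sum_to_one(self, model_a, baseline):
        from phenoclust.preprocess import transform_variables

        fm = transform_variables(baseline, model_a.var_names)
        res = classify_cohort(model_a, fm)
        np.testing.assert_allclose(res.probabilities.sum(axis=1), 1.0, atol=1e-12)

    def test_extra_columns_ignored(self, model_a, baseline):
        from phenoclust.preprocess import transform_variables

        fm_full = transform_variables(baseline, "clinical9")
        fm_min = transform_variables(baseline, model_a.var_names)
        full = classify_cohort(model_a, fm_full)
        minimal = classify_cohort(model_a, fm_min)
        np.testing.assert_allclose(full.probabilities, minimal.probabilities)

    def test_missing_predictor_errors(self, model_a, baseline):
        from phenoclust.preprocess import transform_variables

        fm = transform_variables(baseline, "model_b")  # lacks blood_eos
        with pytest.raises(ValueError, match="predictor"):
            classify_cohort(model_a, fm)


class TestCalculator:
    def test_roundtrip_probabilities_bit_identical(self, model_a, tmp_path):
        path = tmp_path / "calc.csv"
        export_calculator(model_a, path)
        classes, names, coef_raw = import_calculator(path)
        assert classes == model_a.classes
        assert names == model_a.var_names
        rng = np.random.default_rng(4)
        x_raw = model_a.center + rng.standard_normal(len(names)) * model_a.scale
        via_file = calculator_probabilities(coef_raw, x_raw)
        via_model = calculator_probabilities(fold_scaling(model_a), x_raw)
        assert (via_file == via_model).all()

    def test_folded_coefficients_match_scaled_path(self, model_a):
        rng = np.random.default_rng(5)
        x_raw = model_a.center + rng.standard_normal(len(model_a.var_names))
        f_scaled = linear_predictors(model_a, x_raw)
        raw = fold_scaling(model_a)
        f_raw = raw[0] + x_raw @ raw[1:]
        np.testing.assert_allclose(f_raw, f_scaled, atol=1e-10)

    def test_coefficient_table_size(self, model_a, tmp_path):
        path = tmp_path / "calc.csv"
        export_calculator(model_a, path)
        _, names, coef_raw = import_calculator(path)
        assert coef_raw.shape == (len(names) + 1, len(model_a.classes))

    def test_model_json_roundtrip(self, model_a, tmp_path):
        path = tmp_path / "model.json"
        classify.model_to_json(model_a, path)
        back = classify.model_from_json(path)
        np.testing.assert_allclose(back.coef, model_a.coef)
        assert back.classes == model_a.classes
        assert back.variant == model_a.variant
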