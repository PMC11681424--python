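"""Fisher discriminant fitting, preset models, metrics and cluster ratio."""

import numpy as np
import pytest
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from papunmix import (
    FisherDiscriminant,
    LinearDiscriminantModel,
    Patch,
    ValidationError,
    classify,
    cluster_legh_ratio,
    evaluate,
    evaluate_confusion,
    fit_fisher,
    make_two_class_dataset,
    preset_models,
)


class TestFitFisher:
    def test_1d_midpoint_boundary(self):
        model = fit_fisher([[0.0], [0.0]], [[2.0], [2.0]], ridge=1e-9)
        # boundary at x = 1, LEGH side positive
        assert model.decision([1.0]) == pytest.approx(0.0, abs=1e-6)
        assert model.classify([1.5]) == "LEGH"
        assert model.classify([0.5]) == "EC"

    def test_swapping_classes_flips_sign(self, rng):
        a = rng.standard_normal((30, 3))
        b = rng.standard_normal((30, 3)) + 2.0
        m1 = fit_fisher(a, b)
        m2 = fit_fisher(b, a)
        x = rng.standard_normal((10, 3))
        assert np.allclose(m1.decision(x), -m2.decision(x), atol=1e-9)

    def test_separated_gaussians_reach_high_accuracy(self, rng):
        # two 2-D clouds five sigmas apart
        ec = rng.standard_normal((200, 2))
        legh = rng.standard_normal((200, 2)) + np.array([5.0, 0.0])
        model = fit_fisher(ec, legh)
        preds = list(model.classify(ec)) + list(model.classify(legh))
        truth = ["EC"] * 200 + ["LEGH"] * 200
        acc = np.mean([p == t for p, t in zip(preds, truth)])
        assert acc >= 0.99

    def test_affine_shift_invariance_of_labels(self, rng):
        ec = rng.standard_normal((50, 2))
        legh = rng.standard_normal((50, 2)) + 3.0
        shift = np.array([10.0, -4.0])
        m0 = fit_fisher(ec, legh)
        m1 = fit_fisher(ec + shift, legh + shift)
        x = rng.standard_normal((20, 2)) + 1.5
        assert np.array_equal(m0.classify(x), m1.classify(x + shift))

    def test_agrees_with_sklearn_lda_direction(self, rng):
        ec = rng.standard_normal((100, 3))
        legh = rng.standard_normal((100, 3)) + np.array([1.0, 2.0, 0.5])
        model = fit_fisher(ec, legh)
        lda = LinearDiscriminantAnalysis(solver="svd").fit(
            np.vstack([ec, legh]), ["EC"] * 100 + ["LEGH"] * 100
        )
        w_ours = model.weights / np.linalg.norm(model.weights)
        w_lda = lda.coef_[0] / np.linalg.norm(lda.coef_[0])
        assert np.allclose(w_ours, w_lda, atol=1e-6)

    def test_too_few_samples_raise(self):
        with pytest.raises(ValidationError):
            fit_fisher([[0.0]], [[1.0], [2.0]])

    def test_singular_scatter_falls_back_to_ridge(self):
        ec = np.array([[0.0, 0.0], [0.0, 0.0], [0.0, 0.0]])
        legh = np.array([[1.0, 1.0], [1.0, 1.0], [1.0, 1.0]])
        with pytest.warns(UserWarning, match="singular"):
            model = fit_fisher(ec, legh)
        assert model.classify([1.0, 1.0]) == "LEGH"
        assert model.classify([0.0, 0.0]) == "EC"


class TestFisherEstimator:
    def test_sklearn_api_fit_predict(self, rng):
        X, y = make_two_class_dataset(100, 100, seed=3)
        est = FisherDiscriminant().fit(X.to_numpy(), y)
        assert est.score(X.to_numpy(), y) >= 0.95
        assert set(est.predict(X.to_numpy())) <= {"EC", "LEGH"}

    def test_cross_val_integration(self):
        from sklearn.model_selection import cross_val_score

        X, y = make_two_class_dataset(60, 60, seed=5)
        scores = cross_val_score(FisherDiscriminant(), X.to_numpy(), y, cv=3)
        assert scores.mean() >= 0.9


class TestPresets:
    def test_coefficients_are_the_published_constants(self):
        models = preset_models()
        m2 = models["fisher_2d"]
        assert m2.feature_names == ("EY", "OG")
        assert np.allclose(m2.weights, [15.01, -43.55])
        assert m2.bias == pytest.approx(1.454)
        m3 = models["fisher_3d"]
        assert m3.feature_names == ("EY", "LG", "OG")
        assert np.allclose(m3.weights, [41.52, -55.34, -46.79])
        assert m3.bias == pytest.approx(3.263)
        ms = models["srgb"]
        assert ms.feature_names == ("R", "G", "B")
        assert np.allclose(ms.weights, [83.41, -368.9, 365.8])
        assert ms.bias == pytest.approx(-74.22)

    def test_presets_put_og_rich_mucin_on_the_legh_side(self):
        """OG-rich/EY-poor mucin must classify LEGH, EY-rich mucin EC."""
        models = preset_models()
        assert models["fisher_2d"].classify([0.15, 0.40]) == "LEGH"
        assert models["fisher_2d"].classify([0.45, 0.01]) == "EC"
        assert models["fisher_3d"].classify([0.15, 0.08, 0.40]) == "LEGH"
        assert models["fisher_3d"].classify([0.45, 0.12, 0.01]) == "EC"

    def test_decision_values_at_reference_points(self):
        models = preset_models()
        assert models["fisher_2d"].decision([0.0, 0.0]) == pytest.approx(1.454)
        assert models["fisher_3d"].decision([0.0, 0.0, 0.0]) == pytest.approx(3.263)
        assert models["fisher_2d"].decision([1.0, 1.0]) == pytest.approx(
            15.01 - 43.55 + 1.454
        )


class TestClassify:
    def test_tie_goes_to_positive_class(self):
        model = LinearDiscriminantModel(("x",), [1.0], 0.0, positive_label="LEGH")
        assert classify(model, [0.0]) == "LEGH"
        assert classify(model, [-0.1]) == "EC"

    def test_agrees_with_arithmetic_oracle(self, rng):
        model = LinearDiscriminantModel(
            ("a", "b", "c"), rng.standard_normal(3), float(rng.standard_normal()),
        )
        for _ in range(50):
            x = rng.standard_normal(3)
            d = float(model.weights @ x + model.bias)
            assert classify(model, x) == ("LEGH" if d >= 0 else "EC")

    def test_dimension_mismatch_raises(self):
        model = LinearDiscriminantModel(("a", "b"), [1.0, 1.0], 0.0)
        with pytest.raises(Exception):
            model.decision([1.0, 2.0, 3.0])


class TestEvaluate:
    def test_perfect_prediction(self):
        r = evaluate(["EC", "LEGH"] * 5, ["EC", "LEGH"] * 5, "LEGH")
        assert (r.accuracy, r.precision, r.recall, r.f_value) == (1, 1, 1, 1)

    def test_matches_hand_enumerated_oracle_on_random_matrices(self, rng):
        for _ in range(25):
            cm = rng.integers(0, 30, size=(2, 2))
            if cm.sum() == 0:
                continue
            r = evaluate_confusion(cm, "LEGH")
            tp, fn, fp, tn = cm[1, 1], cm[1, 0], cm[0, 1], cm[0, 0]
            assert r.accuracy == pytest.approx((tp + tn) / cm.sum())
            if tp + fp:
                assert r.precision == pytest.approx(tp / (tp + fp))
            if tp + fn:
                assert r.recall == pytest.approx(tp / (tp + fn))
            if r.precision + r.recall:
                assert r.f_value == pytest.approx(
                    2 * r.precision * r.recall / (r.precision + r.recall)
                )

    def test_zero_division_reports_zero_with_flag(self):
        r = evaluate_confusion([[5, 0], [3, 0]], "LEGH")
        assert r.precision == 0.0 and "precision" in r.undefined

    def test_unknown_labels_raise(self):
        with pytest.raises(ValidationError):
            evaluate(["EC"], ["bogus"], "LEGH")

    def test_accuracy_independent_of_positive_class(self, rng):
        cm = rng.integers(1, 20, size=(2, 2))
        assert evaluate_confusion(cm, "LEGH").accuracy == pytest.approx(
            evaluate_confusion(cm, "EC").accuracy
        )


class TestClusterRatio:
    @staticmethod
    def _patch(label, predicted=None):
        return Patch(origin=(0, 0), size=10, label=label, predicted=predicted)

    def test_all_legh(self):
        patches = [self._patch("mucin", "LEGH") for _ in range(4)]
        assert cluster_legh_ratio(patches) == 1.0

    def test_exclusion_of_nucleus_and_background(self):
        patches = (
            [self._patch("mucin", "LEGH")] * 3
            + [self._patch("mucin", "EC")]
            + [self._patch("nucleus")] * 7
            + [self._patch("background")] * 5
        )
        assert cluster_legh_ratio(patches) == pytest.approx(0.75)

    def test_no_mucin_is_undefined(self):
        assert cluster_legh_ratio([self._patch("nucleus")]) is None
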