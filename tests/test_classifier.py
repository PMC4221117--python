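from __future__ import annotations

import math

import numpy as np
import pytest

from hingeshear.classifier import (
    PUBLISHED_MODEL,
    HingeShearClassifier,
    LogisticModel,
    SeparationWarning,
    TrainingSet,
    classify,
    cross_entropy,
    fit,
    loocv,
    precision_report,
    predict,
    read_model,
    read_training_set,
    roc_curve,
    write_model,
    write_training_set,
)
from hingeshear.synth import make_training_set


class TestPublishedModel:
    @pytest.mark.parametrize(
        "counts,expected,places",
        [
            ((10, 2, 2, 6), 0.55, 2),
            ((0, 0, 0, 1), 0.411, 3),
            ((1, 0, 0, 1), 0.470, 3),
            ((1, 0, 0, 0), 0.523, 3),
        ],
    )
    def test_worked_examples(self, counts, expected, places):
        assert round(predict(counts), places) == expected

    def test_all_zero_counts(self):
        # alpha reduces to the bias alone
        assert predict((0, 0, 0, 0)) == pytest.approx(
            1.0 / (1.0 + math.exp(0.1467)), abs=1e-12
        )

    def test_alpha_matches_printed_form(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 15, size=(50, 4)).astype(float)
        expected_alpha = (
            -0.2387 * counts[:, 0]
            - 0.0356 * counts[:, 1]
            + 0.4249 * counts[:, 2]
            + 0.2122 * counts[:, 3]
            + 0.1467
        )
        np.testing.assert_allclose(
            PUBLISHED_MODEL.alpha(counts), expected_alpha, atol=1e-12
        )
        # logit inversion: logit(y) = -alpha
        y = PUBLISHED_MODEL.predict(counts)
        np.testing.assert_allclose(
            np.log(y / (1 - y)), -expected_alpha, atol=1e-10
        )

    def test_monotonicity_signs(self):
        base = np.array([3.0, 3.0, 3.0, 3.0])
        y0 = predict(base)
        for idx, increases in [(0, True), (1, True), (2, False), (3, False)]:
            bumped = base.copy()
            bumped[idx] += 1
            assert (predict(bumped) > y0) is increases


class TestClassify:
    def test_no_contact_before_prediction(self):
        assert classify((0, 0, 0, 0)).value == "no_contact"
        assert classify((0, 0, 0, 0)).y is None

    def test_citrate_synthase_counts_are_mixed(self):
        # full-precision y for N=(10,2,2,6) is 0.5470 < 0.55: mixed,
        # even though it prints as 0.55
        label = classify((10, 2, 2, 6))
        assert label.value == "mixed"
        assert label.y == pytest.approx(0.547, abs=5e-4)

    def test_pure_new_is_hinge(self):
        assert classify((0, 0, 0, 5)).value == "hinge"

    def test_maintained_dominated_is_shear(self):
        assert classify((10, 0, 0, 0)).value == "shear"

    def test_boundaries_inclusive_at_exact_values(self):
        y = predict((0, 0, 0, 5))
        assert classify((0, 0, 0, 5), lower=y, upper=0.9).value == "hinge"
        assert classify((0, 0, 0, 5), lower=y / 2, upper=y).value == "shear"

    def test_invalid_boundaries_error(self):
        with pytest.raises(ValueError, match="boundaries"):
            classify((1, 0, 0, 0), lower=0.7, upper=0.3)


class TestFit:
    def test_recovers_predictions_of_generating_model(self):
        data = make_training_set(PUBLISHED_MODEL, n=400, seed=5)
        model = fit(data)
        y_true = PUBLISHED_MODEL.predict(data.counts)
        y_fit = model.predict(data.counts)
        assert np.mean(np.abs(y_fit - y_true)) < 0.02

    # moderate-overlap regime: guarantees a finite, well-conditioned MLE
    # for the optimizer-agreement checks below
    MILD_HINGE = (2.0, 1.0, 2.0, 3.0)
    MILD_SHEAR = (4.0, 2.0, 1.0, 1.0)

    def mild_set(self, n, seed):
        return make_training_set(
            PUBLISHED_MODEL,
            n=n,
            hinge_means=self.MILD_HINGE,
            shear_means=self.MILD_SHEAR,
            seed=seed,
        )

    def test_matches_statsmodels_logit(self):
        sm = pytest.importorskip("statsmodels.api")
        data = self.mild_set(120, 3)
        model = fit(data)
        design = sm.add_constant(data.counts, prepend=False)
        ref = sm.Logit(data.labels, design).fit(disp=0, method="newton", tol=1e-10)
        np.testing.assert_allclose(model.w, ref.params[:4], atol=1e-6)
        assert model.b == pytest.approx(ref.params[4], abs=1e-6)

    def test_duplicated_data_gives_identical_coefficients(self):
        data = self.mild_set(60, 1)
        doubled = TrainingSet(
            counts=np.vstack([data.counts, data.counts]),
            labels=np.concatenate([data.labels, data.labels]),
            ids=data.ids + [f"{i}-dup" for i in data.ids],
        )
        m1, m2 = fit(data), fit(doubled)
        np.testing.assert_allclose(m1.w, m2.w, atol=1e-7)
        assert m1.b == pytest.approx(m2.b, abs=1e-7)

    def test_single_class_errors(self):
        with pytest.raises(ValueError, match="both classes"):
            fit(
                TrainingSet(
                    counts=np.ones((5, 4)),
                    labels=np.zeros(5, dtype=int),
                    ids=[str(i) for i in range(5)],
                )
            )

    def test_complete_separation_warns(self):
        counts = np.array(
            [[10, 0, 0, 0], [9, 1, 0, 0], [0, 0, 0, 10], [0, 0, 1, 9]], dtype=float
        )
        labels = np.array([1, 1, 0, 0])
        data = TrainingSet(counts=counts, labels=labels, ids=list("abcd"))
        with pytest.warns(SeparationWarning):
            model = fit(data)
        assert np.all(np.isfinite(model.w))

    def test_half_factor_objective_decreases(self):
        data = make_training_set(PUBLISHED_MODEL, n=80, seed=2)
        zero = LogisticModel(w=np.zeros(4), b=0.0)
        fitted = fit(data)
        assert cross_entropy(fitted, data) < cross_entropy(zero, data)


class TestRoc:
    def make(self, labels, scores):
        n = len(labels)
        return (
            TrainingSet(
                counts=np.zeros((n, 4)),
                labels=np.asarray(labels),
                ids=[str(i) for i in range(n)],
            ),
            np.asarray(scores, dtype=float),
        )

    def roc_from_scores(self, labels, scores):
        from hingeshear.classifier import _roc_from_scores

        return _roc_from_scores(np.asarray(labels), np.asarray(scores, dtype=float))

    def test_perfect_separation_auc_one(self):
        r = self.roc_from_scores([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9])
        assert r.auc == pytest.approx(1.0)
        assert r.hull_auc == pytest.approx(1.0)

    def test_constant_scores_auc_half(self):
        r = self.roc_from_scores([0, 1, 0, 1], [0.5, 0.5, 0.5, 0.5])
        assert r.auc == pytest.approx(0.5)

    def test_hand_worked_four_items_vs_threshold_enumeration(self):
        labels = np.array([1, 1, 0, 0])
        scores = np.array([0.9, 0.8, 0.85, 0.7])
        r = self.roc_from_scores(labels, scores)
        # independent oracle: enumerate all thresholds, count swaps
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        pairs = [(p, q) for p in pos for q in neg]
        auc_oracle = sum(1.0 if p > q else 0.5 if p == q else 0.0 for p, q in pairs)
        auc_oracle /= len(pairs)
        assert r.auc == pytest.approx(auc_oracle)
        assert r.hull_auc >= r.auc

    def test_auc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(8)
        labels = rng.integers(0, 2, size=30)
        labels[:2] = [0, 1]
        scores = rng.uniform(size=30)
        r1 = self.roc_from_scores(labels, scores)
        r2 = self.roc_from_scores(labels, np.exp(3 * scores) + 7)
        assert r1.auc == pytest.approx(r2.auc)

    def test_single_class_errors(self):
        data, scores = self.make([1, 1, 1], [0.1, 0.5, 0.9])
        with pytest.raises(ValueError, match="both classes"):
            roc_curve(data, PUBLISHED_MODEL)


class TestLoocv:
    def test_wide_margin_data_gives_auc_one(self):
        counts = np.vstack(
            [
                np.tile([12, 3, 0, 0], (8, 1)),
                np.tile([0, 0, 3, 12], (8, 1)),
            ]
        ).astype(float)
        labels = np.array([1] * 8 + [0] * 8)
        data = TrainingSet(counts=counts, labels=labels, ids=[str(i) for i in range(16)])
        result = loocv(data)
        assert result.roc.auc == pytest.approx(1.0)

    def test_two_items_error(self):
        data = TrainingSet(
            counts=np.ones((2, 4)), labels=np.array([0, 1]), ids=["a", "b"]
        )
        with pytest.raises(ValueError, match="at least 3"):
            loocv(data)

    def test_heldout_length(self):
        data = make_training_set(PUBLISHED_MODEL, n=20, seed=4)
        result = loocv(data)
        assert result.y_heldout.shape == (20,)


class TestPrecision:
    def test_all_correct_is_hundred_percent(self):
        counts = np.vstack(
            [np.tile([10, 0, 0, 0], (5, 1)), np.tile([0, 0, 0, 6], (5, 1))]
        ).astype(float)
        labels = np.array([1] * 5 + [0] * 5)
        data = TrainingSet(counts=counts, labels=labels, ids=[str(i) for i in range(10)])
        rep = precision_report(data)
        assert rep.loc["hinge", "precision_percent"] == pytest.approx(100.0)
        assert rep.loc["shear", "precision_percent"] == pytest.approx(100.0)

    def test_printed_ratio_arithmetic(self):
        # 61 predicted hinge of which 48 truly hinge; 12 predicted shear of
        # which 9 truly shear
        hinge_counts = np.tile([0, 0, 0, 2], (61, 1))
        shear_counts = np.tile([10, 0, 0, 0], (12, 1))
        counts = np.vstack([hinge_counts, shear_counts]).astype(float)
        labels = np.array([0] * 48 + [1] * 13 + [1] * 9 + [0] * 3)
        data = TrainingSet(
            counts=counts, labels=labels, ids=[str(i) for i in range(73)]
        )
        rep = precision_report(data)
        assert rep.loc["hinge", "predicted"] == 61
        assert round(rep.loc["hinge", "precision_percent"]) == 79
        assert rep.loc["shear", "precision_percent"] == pytest.approx(75.0)

    def test_empty_class_undefined_not_zero(self):
        counts = np.tile([0, 0, 0, 6], (5, 1)).astype(float)
        labels = np.array([0] * 5)
        data = TrainingSet(counts=counts, labels=labels, ids=list("abcde"))
        rep = precision_report(data)
        assert rep.loc["shear", "predicted"] == 0
        assert np.isnan(rep.loc["shear", "precision"])


class TestEstimatorApi:
    def test_sklearn_clone_and_get_params(self):
        from sklearn.base import clone

        est = HingeShearClassifier(lower=0.4, upper=0.6)
        cloned = clone(est)
        assert cloned.get_params() == est.get_params()

    def test_fit_predict_shapes(self):
        data = make_training_set(PUBLISHED_MODEL, n=50, seed=6)
        est = HingeShearClassifier().fit(data.counts, data.labels)
        proba = est.predict_proba(data.counts)
        assert proba.shape == (50, 2)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0)
        assert set(est.predict(data.counts)) <= {0, 1}
        assert est.coef_.shape == (1, 4)

    def test_from_published_assign(self):
        est = HingeShearClassifier.from_published()
        labels = est.assign([[0, 0, 0, 0], [0, 0, 0, 5], [10, 0, 0, 0]])
        assert [l.value for l in labels] == ["no_contact", "hinge", "shear"]


class TestFileIO:
    def test_training_set_round_trip(self, tmp_path):
        data = make_training_set(PUBLISHED_MODEL, n=30, seed=9)
        p = tmp_path / "train.tsv"
        write_training_set(data, p)
        back = read_training_set(p)
        np.testing.assert_allclose(back.counts, data.counts)
        np.testing.assert_array_equal(back.labels, data.labels)
        assert back.ids == data.ids

    def test_unknown_label_names_value(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text(
            "id\tn_maint\tn_exchpart\tn_exchpair\tn_new\tlabel\n"
            "x\t1\t0\t0\t0\twobble\n"
        )
        with pytest.raises(ValueError, match="wobble"):
            read_training_set(p)

    def test_model_round_trip(self, tmp_path):
        p = tmp_path / "model.txt"
        write_model(PUBLISHED_MODEL, p)
        back = read_model(p)
        np.testing.assert_allclose(back.w, PUBLISHED_MODEL.w)
        assert back.b == PUBLISHED_MODEL.b
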