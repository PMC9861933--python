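"""GA / SNN / QC classifiers, leave-one-out validation, reports."""

import itertools

import numpy as np
import pytest

from seroprofiler import classify as clf
from tests.conftest import noise_matrix, separable_matrix


class TestQC:
    def test_nearest_centroid_by_hand(self):
        X = np.array([[1.0], [2.0], [3.0], [7.0], [8.0], [9.0]])
        y = np.array(["A", "A", "A", "B", "B", "B"])
        model = clf.train_qc(X, y, clf.QCConfig(top_k=1), classes=["A", "B"])
        # |2.5 - 2| < |2.5 - 8| -> A
        assert model.predict(np.array([[2.5]]))[0] == "A"
        assert model.predict(np.array([[7.5]]))[0] == "B"

    def test_equidistant_tie_goes_to_first_class(self):
        X = np.array([[1.0], [1.0], [9.0], [9.0]])
        y = np.array(["A", "A", "B", "B"])
        model = clf.train_qc(X, y, clf.QCConfig(top_k=1), classes=["A", "B"])
        assert model.predict(np.array([[5.0]]))[0] == "A"

    def test_perfect_separation_full_recognition(self):
        X, y = separable_matrix(margin_sd=8.0, seed=0)
        model = clf.train_qc(X, y)
        rec, per_class, _ = clf.recognition_capability(model, X, y)
        assert rec == 100.0
        assert all(v == 100.0 for v in per_class.values())

    def test_top_k_validated(self):
        X, y = separable_matrix(seed=0)
        with pytest.raises(ValueError):
            clf.train_qc(X, y, clf.QCConfig(top_k=0))


class TestSNN:
    def test_separable_data_high_loocv(self):
        X, y = separable_matrix(n_per_class=10, n_clusters=8,
                                informative=(1, 5), margin_sd=5.0, seed=1)
        config = clf.SNNConfig(prototypes_per_class=2, epochs=60)
        trainer = clf.make_trainer("snn", config, seed=3)
        pct, _, _ = clf.loocv(trainer, X, y)
        assert pct >= 95.0

    def test_single_prototype_equals_nearest_centroid(self):
        X, y = separable_matrix(n_per_class=10, n_clusters=6,
                                informative=(0, 3), margin_sd=6.0, seed=2)
        snn = clf.train_snn(
            X, y, clf.SNNConfig(prototypes_per_class=1, epochs=0), seed=0
        )
        scaler = clf._Scaler.fit(X)
        Z = scaler.transform(X)
        centroids = np.vstack(
            [Z[y == c].mean(axis=0) for c in snn.classes]
        )
        dist = ((Z[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        expected = np.array([snn.classes[i] for i in np.argmin(dist, axis=1)])
        assert (snn.predict(X) == expected).all()

    def test_non_finite_rejected(self):
        X, y = separable_matrix(seed=0)
        X[0, 0] = np.nan
        with pytest.raises(ValueError):
            clf.train_snn(X, y, seed=0)

    def test_deterministic_given_seed(self):
        X, y = separable_matrix(seed=4)
        a = clf.train_snn(X, y, clf.SNNConfig(epochs=20), seed=9)
        b = clf.train_snn(X, y, clf.SNNConfig(epochs=20), seed=9)
        np.testing.assert_array_equal(a.prototypes, b.prototypes)


class TestGA:
    def test_recovers_planted_informative_pair(self):
        X, y = separable_matrix(n_per_class=50, n_clusters=20,
                                informative=(3, 11), margin_sd=4.0, seed=5)
        config = clf.GAConfig(subset_min=2, subset_max=5, population=30,
                              generations=20)
        hits = 0
        for seed in range(5):
            model = clf.train_ga(X, y, config, seed=seed)
            if {3, 11} <= set(model.selected.tolist()):
                hits += 1
        assert hits >= 4

    def test_exhaustive_pair_search_confirms_optimum(self):
        """The planted informative pair is the fitness-optimal 2-subset
        over all C(20, 2) pairs (the GA oracle)."""
        X, y = separable_matrix(n_per_class=50, n_clusters=20,
                                informative=(3, 11), margin_sd=4.0, seed=5)
        y_idx = np.array([0 if c == "allergy" else 1 for c in y])
        folds = clf._make_folds(y_idx, 3, seed=0)
        best = max(
            itertools.combinations(range(20), 2),
            key=lambda pair: clf.centroid_cv_fitness(
                X, y_idx, np.array(pair), folds, 2
            ),
        )
        assert set(best) == {3, 11}

    def test_zero_generations_reduces_to_initial_population(self):
        X, y = separable_matrix(seed=6)
        config = clf.GAConfig(generations=0, population=8)
        a = clf.train_ga(X, y, config, seed=1)
        b = clf.train_ga(X, y, config, seed=1)
        np.testing.assert_array_equal(a.selected, b.selected)

    def test_subset_all_generations_zero_equals_base_classifier(self):
        X, y = separable_matrix(n_per_class=8, n_clusters=5,
                                informative=(0, 2), margin_sd=4.0, seed=7)
        config = clf.GAConfig(subset_min=5, subset_max=5, population=4,
                              generations=0)
        model = clf.train_ga(X, y, config, seed=0)
        assert model.selected.tolist() == [0, 1, 2, 3, 4]
        scaler = clf._Scaler.fit(X)
        Z = scaler.transform(X)
        centroids = np.vstack([Z[y == c].mean(axis=0) for c in model.classes])
        dist = ((Z[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        expected = np.array(
            [model.classes[i] for i in np.argmin(dist, axis=1)]
        )
        assert (model.predict(X) == expected).all()

    def test_small_population_rejected(self):
        X, y = separable_matrix(seed=0)
        with pytest.raises(ValueError):
            clf.train_ga(X, y, clf.GAConfig(population=2), seed=0)


class TestPredictionInterface:
    def test_scores_sum_to_one(self):
        X, y = separable_matrix(seed=8)
        for kind in ("qc", "snn", "ga"):
            config = {"qc": None, "snn": clf.SNNConfig(epochs=10),
                      "ga": clf.GAConfig(population=8, generations=2)}[kind]
            model = clf.make_trainer(kind, config, seed=0)(X, y)
            scores = model.predict_scores(X[:5])
            np.testing.assert_allclose(scores.sum(axis=1), 1.0, atol=1e-9)

    def test_dimension_mismatch_rejected(self):
        X, y = separable_matrix(seed=8)
        model = clf.train_qc(X, y)
        with pytest.raises(ValueError, match="cluster intensities"):
            model.predict(X[:, :5])

    def test_zero_vector_low_confidence_flag(self):
        X = np.array([[1.0, 1.0], [1.2, 0.9], [4.0, 4.2], [4.1, 3.9]])
        y = np.array(["allergy", "allergy", "control", "control"])
        model = clf.train_snn(
            X, y, clf.SNNConfig(prototypes_per_class=1, epochs=5), seed=0
        )
        pred = clf.classify(model, np.zeros(2))
        assert pred.label in model.classes
        assert sum(pred.scores.values()) == pytest.approx(1.0)

    def test_training_sample_classified_as_own_label(self):
        X, y = separable_matrix(margin_sd=8.0, seed=9)
        model = clf.train_qc(X, y)
        pred = clf.classify(model, X[0])
        assert pred.label == y[0]


class TestValidation:
    def test_loocv_perfectly_separable(self):
        X, y = separable_matrix(n_per_class=8, n_clusters=6,
                                informative=(1, 4), margin_sd=8.0, seed=10)
        trainer = clf.make_trainer("qc", clf.QCConfig(top_k=3))
        pct, per_class, confusion = clf.loocv(trainer, X, y)
        assert pct == 100.0
        total = sum(sum(row.values()) for row in confusion.values())
        assert total == len(y)

    def test_too_few_samples_rejected(self):
        X = np.random.default_rng(0).random((2, 3))
        with pytest.raises(ValueError):
            clf.loocv(clf.make_trainer("qc"), X, np.array(["a", "b"]))

    def test_class_with_single_member_rejected(self):
        X = np.random.default_rng(0).random((5, 3))
        y = np.array(["a", "a", "a", "a", "b"])
        with pytest.raises(ValueError):
            clf.loocv(clf.make_trainer("qc"), X, y)

    def test_report_round_trip_and_determinism(self):
        X, y = separable_matrix(n_per_class=8, n_clusters=6,
                                informative=(1, 4), margin_sd=5.0, seed=11)
        report = clf.validate(
            "snn", X=X, y=y, config=clf.SNNConfig(epochs=15), seed=2
        )
        back = clf.ValidationReport.from_json(report.to_json())
        assert back == report
        report2 = clf.validate(
            "snn", X=X, y=y, config=clf.SNNConfig(epochs=15), seed=2
        )
        assert report2 == report

    def test_recognition_at_least_loocv_on_separable_demo(self):
        X, y = separable_matrix(n_per_class=10, n_clusters=10,
                                informative=(2, 7), margin_sd=5.0, seed=12)
        for kind, config in (
            ("qc", clf.QCConfig(top_k=4)),
            ("snn", clf.SNNConfig(prototypes_per_class=2, epochs=40)),
            ("ga", clf.GAConfig(subset_min=2, subset_max=5, population=12,
                                generations=5)),
        ):
            report = clf.validate(kind, X=X, y=y, config=config, seed=3)
            assert report.recognition_pct >= report.cross_validation_pct
            assert 0 <= report.cross_validation_pct <= 100

    def test_constant_features_near_chance(self):
        rng = np.random.default_rng(13)
        X = np.full((24, 5), 2.0) + rng.normal(0, 1e-9, (24, 5))
        y = np.array(["allergy"] * 12 + ["control"] * 12)
        pct, _, _ = clf.loocv(clf.make_trainer("qc", clf.QCConfig(top_k=3)), X, y)
        assert 20.0 <= pct <= 80.0

    def test_report_frame_layout(self):
        X, y = separable_matrix(n_per_class=8, n_clusters=6,
                                informative=(1, 4), margin_sd=5.0, seed=14)
        report = clf.validate("qc", X=X, y=y, config=clf.QCConfig(top_k=3))
        frame = report.to_frame()
        assert "Cross-validation (%)" in frame.index
        assert "Recognition capability (%)" in frame.index
        assert frame.columns.tolist() == ["QC"]


class TestNullBehaviour:
    def test_all_noise_fitness_near_chance(self):
        """Internal CV fitness on pure noise sits near chance once the
        cohort is large enough to bound the selection optimism."""
        config = clf.GAConfig(subset_min=2, subset_max=5, population=12,
                              generations=5)
        fits = []
        for seed in range(10):
            X, y = noise_matrix(n1=200, n2=200, n_clusters=10, seed=seed)
            fits.append(clf.train_ga(X, y, config, seed=seed).fitness)
        assert abs(float(np.mean(fits)) - 0.5) <= 0.10
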