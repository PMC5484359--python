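"""AdaBoostM1 loop, weak learners and forest tree-count tuning."""

import math

import numpy as np
import pytest

from imbalmrs import (
    Cohort,
    FitError,
    ValidationError,
    WeakLearnerSpec,
    adaboost_m1_predict,
    adaboost_m1_train,
    forest_tune,
    learner_from_name,
    weak_learner_fit,
)
from imbalmrs.learners import DEFAULT_TREE_GRIDS, BoostedEnsemble


class FixedPredictor:
    """Stub learner with a hard-wired prediction rule."""

    def __init__(self, rule):
        self.rule = rule

    def predict(self, x):
        return np.array([self.rule(row) for row in np.atleast_2d(x)], dtype=object)


def separable_xy(n=20, seed=0):
    rng = np.random.default_rng(seed)
    x = np.vstack([rng.normal(-5, 0.5, size=(n, 2)), rng.normal(5, 0.5, size=(n, 2))])
    y = np.array(["a"] * n + ["b"] * n, dtype=object)
    return x, y


class TestAdaboostTrain:
    def test_perfect_weak_learner_stops_after_round_one(self):
        x, y = separable_xy()
        factory = lambda xx, yy, ww, ss: FixedPredictor(
            lambda row: "a" if row[0] < 0 else "b"
        )
        ensemble = adaboost_m1_train(x, y, spec=factory, max_rounds=50, seed=0)
        assert ensemble.n_rounds_used == 1

    def test_quarter_error_gives_log_three_voting_weight(self):
        # weak learner errs on exactly 5 of 20 uniformly weighted points:
        # eps = 0.25, voting weight log((1 - 0.25)/0.25) = log 3
        x = np.arange(20, dtype=float).reshape(-1, 1)
        y = np.array(["a"] * 20, dtype=object)
        y[:10] = "b"

        def rule(row):
            truth = "b" if row[0] < 10 else "a"
            return "a" if row[0] < 5 else truth  # wrong on rows 0..4

        tracked_weights = []

        def factory(xx, yy, ww, ss):
            tracked_weights.append(ww.copy())
            return FixedPredictor(rule)

        ensemble = adaboost_m1_train(x, y, spec=factory, max_rounds=2, seed=0)
        assert ensemble.member_weights[0] == pytest.approx(math.log(3.0))
        # weights after the update still sum to one
        assert tracked_weights[1].sum() == pytest.approx(1.0)
        # misclassified points gained weight by factor (1-eps)/eps = 3
        ratio = tracked_weights[1][0] / tracked_weights[1][10]
        assert ratio == pytest.approx(3.0)

    def test_high_error_round_one_keeps_single_unweighted_learner(self):
        x = np.arange(10, dtype=float).reshape(-1, 1)
        y = np.array(["a"] * 5 + ["b"] * 5, dtype=object)
        factory = lambda xx, yy, ww, ss: FixedPredictor(lambda row: "b")  # eps 0.5
        ensemble = adaboost_m1_train(x, y, spec=factory, max_rounds=10, seed=0)
        assert ensemble.n_rounds_used == 1
        assert ensemble.member_weights == [1.0]

    def test_training_error_non_increasing_with_moderate_rounds(self):
        # NB weak learner on an overlapping 2-class problem: every round has
        # eps < 0.5 and the cumulative-ensemble training error never rises
        rng = np.random.default_rng(3)
        x = np.vstack([rng.normal(-1, 1.2, size=(30, 3)), rng.normal(1, 1.2, size=(30, 3))])
        y = np.array(["a"] * 30 + ["b"] * 30, dtype=object)
        ensemble = adaboost_m1_train(
            x, y, spec=WeakLearnerSpec("naive_bayes"), max_rounds=8, seed=0
        )
        errors = []
        for upto in range(1, ensemble.n_rounds_used + 1):
            partial = BoostedEnsemble(
                members=ensemble.members[:upto],
                member_weights=ensemble.member_weights[:upto],
                classes=ensemble.classes,
                n_rounds_used=upto,
                max_rounds=ensemble.max_rounds,
            )
            errors.append(float((partial.predict(x) != y).mean()))
        assert all(b <= a + 1e-12 for a, b in zip(errors, errors[1:]))

    def test_single_round_equals_the_bare_weak_learner(self):
        rng = np.random.default_rng(4)
        x = np.vstack([rng.normal(-1, 1, size=(15, 2)), rng.normal(1, 1, size=(15, 2))])
        y = np.array(["a"] * 15 + ["b"] * 15, dtype=object)
        spec = WeakLearnerSpec("naive_bayes")
        ensemble = adaboost_m1_train(x, y, spec=spec, max_rounds=1, seed=5)
        bare = weak_learner_fit(spec, x, y, np.full(30, 1 / 30), seed=5)
        assert np.array_equal(ensemble.predict(x), bare.predict(x))

    def test_voting_weights_positive_and_finite(self, cohort90):
        ensemble = adaboost_m1_train(
            cohort90, spec=WeakLearnerSpec("naive_bayes"), max_rounds=10, seed=0
        )
        assert all(w > 0 and math.isfinite(w) for w in ensemble.member_weights)

    def test_single_class_training_rejected(self):
        x = np.zeros((4, 2))
        y = np.array(["a"] * 4, dtype=object)
        with pytest.raises(ValidationError):
            adaboost_m1_train(x, y, spec=WeakLearnerSpec("naive_bayes"))


class TestAdaboostPredict:
    def _ensemble(self, members, weights):
        return BoostedEnsemble(
            members=members,
            member_weights=weights,
            classes=["A", "B", "C"],
            n_rounds_used=len(members),
            max_rounds=10,
        )

    def test_single_member_identity(self):
        member = FixedPredictor(lambda row: "B")
        ensemble = self._ensemble([member], [2.0])
        assert list(ensemble.predict(np.zeros((3, 1)))) == ["B", "B", "B"]

    def test_heavier_member_wins_disagreement(self):
        heavy = FixedPredictor(lambda row: "A")
        light = FixedPredictor(lambda row: "C")
        ensemble = self._ensemble([heavy, light], [2.0, 1.0])
        assert list(ensemble.predict(np.zeros((1, 1)))) == ["A"]

    def test_plurality_of_equal_weights(self):
        members = [
            FixedPredictor(lambda row: "A"),
            FixedPredictor(lambda row: "B"),
            FixedPredictor(lambda row: "A"),
        ]
        ensemble = self._ensemble(members, [1.0, 1.0, 1.0])
        assert list(ensemble.predict(np.zeros((1, 1)))) == ["A"]

    def test_exact_tie_breaks_toward_earlier_class_name(self):
        members = [FixedPredictor(lambda row: "C"), FixedPredictor(lambda row: "B")]
        ensemble = self._ensemble(members, [1.0, 1.0])
        assert list(ensemble.predict(np.zeros((1, 1)))) == ["B"]

    def test_empty_ensemble_rejected(self):
        ensemble = self._ensemble([FixedPredictor(lambda row: "A")], [1.0])
        ensemble.members, ensemble.member_weights = [], []
        with pytest.raises(ValidationError):
            adaboost_m1_predict(ensemble, np.zeros((1, 1)))


class TestWeakLearnerFit:
    def test_zero_weight_samples_have_no_influence_on_native_fit(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(30, 2))
        y = np.array(["a"] * 15 + ["b"] * 15, dtype=object)
        w = np.ones(30)
        w[20:] = 0.0  # poison block gets zero weight
        poisoned = x.copy()
        poisoned[20:] += 1000.0
        spec = WeakLearnerSpec("naive_bayes")
        a = weak_learner_fit(spec, x, y, w, seed=0)
        b = weak_learner_fit(spec, poisoned, y, w, seed=0)
        grid = rng.normal(size=(10, 2))
        assert np.array_equal(a.predict(grid), b.predict(grid))

    def test_all_weight_on_one_class_raises(self):
        x = np.random.default_rng(0).normal(size=(10, 2))
        y = np.array(["a"] * 5 + ["b"] * 5, dtype=object)
        w = np.array([1.0] * 5 + [0.0] * 5)
        with pytest.raises(FitError):
            weak_learner_fit(WeakLearnerSpec("naive_bayes"), x, y, w)

    def test_lda_recovers_the_analytic_discriminant_direction(self):
        # equal spherical covariances: Fisher direction is the mean difference
        rng = np.random.default_rng(1)
        mu_a, mu_b = np.array([0.0, 0.0]), np.array([3.0, 1.0])
        x = np.vstack(
            [rng.normal(mu_a, 1.0, size=(400, 2)), rng.normal(mu_b, 1.0, size=(400, 2))]
        )
        y = np.array(["a"] * 400 + ["b"] * 400, dtype=object)
        model = weak_learner_fit(WeakLearnerSpec("lda"), x, y, np.ones(800), seed=0)
        direction = model.coef_[0] / np.linalg.norm(model.coef_[0])
        expected = (mu_b - mu_a) / np.linalg.norm(mu_b - mu_a)
        assert abs(float(direction @ expected)) > 0.98

    def test_unknown_family_rejected(self):
        with pytest.raises(Exception):
            WeakLearnerSpec("gradient_boosting")

    @pytest.mark.parametrize("family", ["naive_bayes", "svm_rbf", "ann", "lda"])
    def test_each_family_fits_and_predicts_three_classes(self, family, cohort90):
        spec = WeakLearnerSpec(
            family, {"hidden_sizes": (4,), "max_epochs": 30} if family == "ann" else {}
        )
        n = cohort90.n_samples
        model = weak_learner_fit(spec, cohort90.features, cohort90.labels, np.ones(n) / n, seed=0)
        pred = model.predict(cohort90.features)
        assert set(pred) <= set(cohort90.class_names)


class TestForestTune:
    def test_singleton_grid_selected(self, cohort90):
        config = forest_tune(cohort90, [40], folds=3, seed=0)
        assert config.selected_trees == 40

    def test_default_grids_cover_published_operating_points(self):
        assert set(range(25, 91)).issuperset(set()) is True
        assert min(DEFAULT_TREE_GRIDS["profile"]) == 25
        assert max(DEFAULT_TREE_GRIDS["profile"]) == 90
        assert min(DEFAULT_TREE_GRIDS["spectra"]) == 78
        assert max(DEFAULT_TREE_GRIDS["spectra"]) == 170

    def test_cleanly_separable_data_selects_the_smallest_count(self):
        rng = np.random.default_rng(0)
        features = np.vstack(
            [rng.normal(c * 50, 0.1, size=(12, 3)) for c in range(3)]
        )
        cohort = Cohort(
            features=features,
            feature_names=["f0", "f1", "f2"],
            labels=np.array(sum([[f"c{c}"] * 12 for c in range(3)], []), dtype=object),
            sample_ids=np.array([f"S{i}" for i in range(36)], dtype=object),
        )
        config = forest_tune(cohort, [10, 20, 40], folds=3, seed=1)
        assert config.selected_trees == 10

    def test_empty_grid_rejected(self, cohort90):
        with pytest.raises(ValidationError):
            forest_tune(cohort90, [], folds=3)

    def test_forest_learner_deterministic_given_seed(self, cohort90):
        lc = learner_from_name("random-forest", n_trees=25)
        a = lc.fit(cohort90.features, cohort90.labels, seed=3)
        b = lc.fit(cohort90.features, cohort90.labels, seed=3)
        assert np.array_equal(a.predict(cohort90.features), b.predict(cohort90.features))
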