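"""Threshold, sequential, LOOCV-threshold and logistic classifiers."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rsvp_screen import classification as clf
from rsvp_screen.errors import ConfigError, ConvergenceError, SingleClassError


class TestThresholdPredict:
    @pytest.mark.parametrize(
        "score, cutoff, expected",
        [
            (5, 6, "CI"),
            (6, 6, "HC"),  # boundary scores classify HC (strict below)
            (29, 29, "HC"),
            (28, 29, "CI"),
            (41, 29, "HC"),
        ],
    )
    def test_strict_below_rule(self, score, cutoff, expected):
        assert clf.threshold_predict(score, clf.ThresholdRule(cutoff)) == expected

    @given(
        score=st.floats(-100, 100, allow_nan=False),
        bump=st.floats(0, 50, allow_nan=False),
        cutoff=st.floats(-100, 100, allow_nan=False),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_monotone_in_score(self, score, bump, cutoff):
        """Raising a score never flips HC to CI."""
        rule = clf.ThresholdRule(cutoff)
        if clf.threshold_predict(score, rule) == "HC":
            assert clf.threshold_predict(score + bump, rule) == "HC"

    def test_infinite_cutoff_rejected(self):
        with pytest.raises(ConfigError):
            clf.ThresholdRule(float("inf"))


class TestSequentialPredict:
    @pytest.mark.parametrize(
        "cdt, photo, expected",
        [
            (5, 45, "CI"),  # fails CDT gate
            (7, 25, "CI"),  # passes CDT, fails Phototest
            (7, 40, "HC"),  # passes both
            (6, 29, "HC"),  # both exactly at cutoff
        ],
    )
    def test_two_gate_rule(self, cdt, photo, expected):
        assert clf.sequential_predict(cdt, photo) == expected

    @given(
        cdt=st.integers(0, 7),
        photo=st.integers(0, 50),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_sequential_ci_set_contains_cdt_ci_set(self, cdt, photo):
        cdt_rule = clf.ThresholdRule(clf.CDT_CUTOFF)
        if clf.threshold_predict(cdt, cdt_rule) == "CI":
            assert clf.sequential_predict(cdt, photo) == "CI"


def brute_force_best_accuracy(scores, labels):
    """Oracle: scan a dense cutoff set and report the best training accuracy."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=object)
    distinct = np.unique(scores)
    cuts = np.concatenate(
        [[distinct[0] - 1], (distinct[:-1] + distinct[1:]) / 2, [distinct[-1] + 1]]
    )
    return max(
        float(np.mean(np.where(scores < c, "CI", "HC") == labels)) for c in cuts
    )


class TestFitOptimalThreshold:
    def test_separable_midpoint(self):
        rule = clf.fit_optimal_threshold([10, 20, 50, 60], ["CI", "CI", "HC", "HC"])
        assert rule.cutoff == 35.0
        assert clf.threshold_predict(20, rule) == "CI"
        assert clf.threshold_predict(50, rule) == "HC"

    def test_degenerate_all_identical_scores(self):
        # whatever the cutoff, accuracy is the majority-class rate; the
        # smallest candidate wins the tie
        rule = clf.fit_optimal_threshold([5, 5, 5], ["CI", "HC", "HC"])
        assert rule.cutoff == 4.0

    def test_single_class_rejected(self):
        with pytest.raises(SingleClassError):
            clf.fit_optimal_threshold([1, 2], ["CI", "CI"])

    def test_matches_exhaustive_scan_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 15))
            scores = rng.integers(0, 10, size=n).astype(float)
            labels = np.where(rng.random(n) < 0.5, "CI", "HC")
            if len(set(labels)) < 2:
                continue
            rule = clf.fit_optimal_threshold(scores, labels)
            acc = float(np.mean(np.where(scores < rule.cutoff, "CI", "HC") == labels))
            assert acc == pytest.approx(brute_force_best_accuracy(scores, labels))


class TestLoocvThreshold:
    def test_separable_data_all_correct(self):
        scores = [10, 12, 14, 50, 55, 60]
        labels = ["CI"] * 3 + ["HC"] * 3
        preds = clf.loocv_threshold(scores, labels)
        assert list(preds.predicted) == labels
        assert len(preds.fold_artifacts) == len(scores)

    def test_matches_independent_loocv_loop(self, default_cohort):
        """Fold thresholds and predictions equal an independently coded loop."""
        from rsvp_screen import performance as pf

        scores = np.array(
            [
                pf.compute_global(pf.compute_curve(r.outcomes)).global_am
                for r in default_cohort
            ]
        )
        labels = np.array([r.group for r in default_cohort], dtype=object)
        preds = clf.loocv_threshold(scores, labels)
        for i in range(len(scores)):
            mask = np.ones(len(scores), bool)
            mask[i] = False
            rule = clf.fit_optimal_threshold(scores[mask], labels[mask])
            assert preds.fold_artifacts[i] == rule.cutoff
            assert preds.predicted[i] == clf.threshold_predict(scores[i], rule)

    def test_leakage_guard_threshold(self):
        """Perturbing the held-out participant's score never changes that
        fold's fitted threshold."""
        rng = np.random.default_rng(8)
        scores = rng.normal(50, 15, size=12)
        labels = np.array(["CI"] * 6 + ["HC"] * 6, dtype=object)
        base = clf.loocv_threshold(scores, labels)
        for i in range(len(scores)):
            mutated = scores.copy()
            mutated[i] += 1000.0
            assert (
                clf.loocv_threshold(mutated, labels).fold_artifacts[i]
                == base.fold_artifacts[i]
            )

    def test_needs_three_participants(self):
        with pytest.raises(ConfigError):
            clf.loocv_threshold([1, 2], ["CI", "HC"])


def simulate_logistic(rng, n, coef, intercept):
    X = rng.normal(size=(n, len(coef)))
    p = 1 / (1 + np.exp(-(X @ coef + intercept)))
    y = np.where(rng.random(n) < p, "CI", "HC")
    return X, y


class TestFitLogistic:
    def test_separable_near_unpenalized(self):
        X = np.array([[0.0], [1.0], [10.0], [11.0]])
        y = np.array(["CI", "CI", "HC", "HC"], dtype=object)
        model = clf.fit_logistic(X, y, clf.LogisticSpec(c=1e5), strict=False)
        assert list(model.predict(X)) == list(y)

    def test_strong_penalty_collapses_to_majority(self, rng):
        X, y = simulate_logistic(rng, 30, np.array([2.0, -1.0]), 0.0)
        y[:20] = "HC"  # force an HC majority
        model = clf.fit_logistic(X, y, clf.LogisticSpec(penalty="l2", c=1e-7))
        assert np.allclose(model.coef, 0.0, atol=1e-4)
        assert set(model.predict(X)) == {"HC"}

    @pytest.mark.parametrize("penalty", ["l1", "l2"])
    def test_parameter_recovery(self, penalty, rng):
        """Near-unpenalized fit on a large simulation recovers the generating
        coefficients within 10% relative error."""
        coef = np.array([1.5, -2.0, 0.8])
        X, y = simulate_logistic(rng, 20_000, coef, 0.3)
        spec = clf.LogisticSpec(penalty=penalty, c=1e5, standardize=False)
        model = clf.fit_logistic(X, y, spec, strict=False)
        assert np.all(np.abs(model.coef - coef) / np.abs(coef) < 0.10)

    def test_single_class_rejected(self):
        with pytest.raises(SingleClassError):
            clf.fit_logistic(np.zeros((3, 2)), ["CI"] * 3, clf.LogisticSpec())

    def test_nonconvergence_raises_with_iteration_count(self):
        # perfectly separable single feature at huge C cannot reach tol=1e-8
        X = np.array([[-2.0], [-1.0], [1.0], [2.0]] * 3)
        y = np.array((["CI"] * 2 + ["HC"] * 2) * 3, dtype=object)
        spec = clf.LogisticSpec(penalty="l1", c=1e7)
        with pytest.raises(ConvergenceError) as exc:
            clf.fit_logistic(X, y, spec, strict=True)
        assert exc.value.n_iter == 10_000

    def test_nan_features_rejected(self):
        X = np.array([[1.0], [np.nan], [2.0], [3.0]])
        with pytest.raises(ConfigError):
            clf.fit_logistic(X, ["CI", "CI", "HC", "HC"], clf.LogisticSpec())


class TestGridSearchLoocv:
    def test_default_grid_size(self):
        assert len(clf.DEFAULT_PENALTIES) * len(clf.DEFAULT_C_GRID) == 30

    def test_single_point_grid_returns_it(self, rng):
        X, y = simulate_logistic(rng, 12, np.array([3.0]), 0.0)
        res = clf.grid_search_loocv(X, y, penalties=["l2"], c_values=[1.0])
        assert res.best_spec == clf.LogisticSpec(penalty="l2", c=1.0)
        assert len(res.grid_accuracies) == 1

    def test_selected_accuracy_dominates_grid(self, default_cohort):
        from rsvp_screen import performance as pf

        X, y = pf.build_feature_matrix(default_cohort)
        res = clf.grid_search_loocv(X, y)
        assert res.accuracy == max(res.grid_accuracies.values())
        assert res.grid_accuracies[(res.best_spec.penalty, res.best_spec.c)] == (
            res.accuracy
        )
        # tie-break: no grid point with equal accuracy has smaller C, and none
        # with equal accuracy and equal C is l2 when the winner is l1
        for (pen, c), acc in res.grid_accuracies.items():
            if acc == res.accuracy:
                assert c >= res.best_spec.c
                if c == res.best_spec.c and res.best_spec.penalty == "l1":
                    assert pen == "l1"

    def test_leakage_guard_logistic(self, rng):
        """Perturbing the held-out row's features leaves that fold's
        prediction machinery (fitted on the others) unchanged, so every
        OTHER fold's prediction is unaffected too except through row i
        itself."""
        X, y = simulate_logistic(rng, 10, np.array([2.0, 1.0]), 0.0)
        if len(set(y)) < 2:
            y[0] = "CI" if y[0] == "HC" else "HC"
        spec = clf.LogisticSpec(penalty="l2", c=1.0)
        i = 3
        Xm = X.copy()
        Xm[i] += 100.0
        mask = np.arange(len(y)) != i
        base_model = clf.fit_logistic(X[mask], y[mask], spec, strict=False)
        mut_model = clf.fit_logistic(Xm[mask], y[mask], spec, strict=False)
        assert np.allclose(base_model.coef, mut_model.coef)
        assert base_model.intercept == pytest.approx(mut_model.intercept)

    def test_empty_grid_rejected(self):
        with pytest.raises(ConfigError):
            clf.grid_search_loocv(np.zeros((4, 2)), ["CI", "CI", "HC", "HC"], penalties=[])
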