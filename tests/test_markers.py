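import numpy as np
import pytest

from popmarker import (
    MarkerSet,
    PropertySample,
    SVSettings,
    classification_rates,
    evaluate_combinations,
    regression_errors,
    roc_and_auc,
    train_classifier,
    train_regressor,
)


def delta_sample(x, labels, names=None):
    x = np.asarray(x, float)
    if x.ndim == 1:
        x = x[:, None]
    names = names or [f"p{j}" for j in range(x.shape[1])]
    return PropertySample(x, names, "delta", labels=np.asarray(labels))


def phi_sample(x, values, names=None):
    x = np.asarray(x, float)
    if x.ndim == 1:
        x = x[:, None]
    names = names or [f"p{j}" for j in range(x.shape[1])]
    return PropertySample(x, names, "phi", values=np.asarray(values, float))


@pytest.fixture(scope="module")
def separable():
    rng = np.random.default_rng(0)
    lo = np.exp(rng.normal(-1.0, 0.15, 200))
    hi = np.exp(rng.normal(1.0, 0.15, 200))
    x = np.concatenate([lo, hi])
    labels = np.r_[np.full(200, -1), np.full(200, 1)]
    return delta_sample(x, labels)


@pytest.fixture(scope="module")
def uninformative():
    """Labels independent of the single feature."""
    rng = np.random.default_rng(1)
    x = np.exp(rng.normal(0, 0.4, 1200))
    labels = np.where(rng.random(1200) < 0.5, 1, -1)
    train = delta_sample(x[:600], labels[:600])
    test = delta_sample(x[600:], labels[600:])
    return train, test


M0 = MarkerSet((0,), ("p0",))


class TestClassifier:
    def test_separable_perfect_training_accuracy(self, separable):
        clf = train_classifier(separable, M0)
        assert np.all(clf.predict(separable.parameters) == separable.labels)

    def test_single_class_rejected(self):
        sample = delta_sample([1.0, 2.0, 3.0], [1, 1, 1])
        with pytest.raises(ValueError, match="single class"):
            train_classifier(sample, M0)

    def test_perfect_predictor_rates_and_auc(self, separable):
        clf = train_classifier(separable, M0)
        tp, fp = classification_rates(clf, separable)
        assert (tp, fp) == (1.0, 0.0)
        report = roc_and_auc(clf, separable)
        assert report.auc == pytest.approx(1.0, abs=1e-12)

    def test_uninformative_marker_is_chance(self, uninformative):
        train, test = uninformative
        clf = train_classifier(train, M0)
        tp, fp = classification_rates(clf, test)
        # no information: TP and FP agree within binomial noise
        assert abs(tp - fp) < 3 * np.sqrt(0.25 / 300 + 0.25 / 300)
        report = roc_and_auc(clf, test)
        assert abs(report.auc - 0.5) < 3 * np.sqrt(1 / 12 / 300)

    def test_log_transform_requires_positive(self):
        sample = delta_sample([-1.0, 1.0, 2.0, 3.0], [1, -1, 1, -1])
        with pytest.raises(ValueError, match="positive"):
            train_classifier(sample, M0)

    def test_deterministic_given_inputs(self, separable):
        c1 = train_classifier(separable, M0)
        c2 = train_classifier(separable, M0)
        x = separable.parameters
        np.testing.assert_array_equal(c1.decision_value(x), c2.decision_value(x))


class TestROC:
    def test_invariants(self, uninformative):
        train, test = uninformative
        report = roc_and_auc(train_classifier(train, M0), test)
        roc = report.roc
        assert tuple(roc[0]) == (0.0, 0.0)
        assert tuple(roc[-1]) == (1.0, 1.0)
        assert np.all(np.diff(roc[:, 0]) >= 0)
        assert report.auc == pytest.approx(
            np.trapezoid(roc[:, 1], roc[:, 0]), abs=1e-12
        )

    def test_native_rates_lie_on_curve(self, uninformative):
        train, test = uninformative
        clf = train_classifier(train, M0)
        tp, fp = classification_rates(clf, test)
        roc = roc_and_auc(clf, test).roc
        # the native threshold (decision value 0) is one of the sweep points
        distances = np.hypot(roc[:, 0] - fp, roc[:, 1] - tp)
        assert distances.min() < 1e-12

    def test_auc_invariant_under_monotone_score_transform(self, uninformative):
        train, test = uninformative
        clf = train_classifier(train, M0)
        from sklearn.metrics import roc_auc_score

        scores = clf.decision_value(test.parameters)
        y = (test.labels == 1).astype(int)
        a1 = roc_auc_score(y, scores)
        a2 = roc_auc_score(y, np.tanh(3 * scores) + 7)
        assert a1 == pytest.approx(a2, abs=1e-12)


class TestRegressor:
    def test_constant_target_within_epsilon(self):
        rng = np.random.default_rng(2)
        x = np.exp(rng.normal(0, 0.3, 100))
        sample = phi_sample(x, np.full(100, 3.0))
        reg = train_regressor(sample, M0)
        pred = reg.predict(sample.parameters)
        assert np.all(np.abs(pred - 3.0) <= 0.01 + 1e-9)

    def test_smooth_function_consistency(self):
        rng = np.random.default_rng(3)
        x = np.exp(rng.normal(0, 0.4, 3000))
        phi = 5.0 / x
        train = phi_sample(x[:2000], phi[:2000])
        test = phi_sample(x[2000:], phi[2000:])
        reg = train_regressor(train, M0)
        report = regression_errors(reg, test)
        assert report.summary["median"] < 0.05

    def test_uninformative_no_better_than_median_baseline(self):
        rng = np.random.default_rng(4)
        x = np.exp(rng.normal(0, 0.4, 2000))
        phi = np.exp(rng.normal(1.0, 0.5, 2000))  # independent of x
        train = phi_sample(x[:1000], phi[:1000])
        test = phi_sample(x[1000:], phi[1000:])
        reg = train_regressor(train, M0)
        report = regression_errors(reg, test)
        baseline = np.median(
            np.abs(phi[1000:] - np.median(phi[:1000])) / phi[1000:]
        )
        assert report.summary["median"] > 0.8 * baseline

    def test_scale_error_magnitude_one(self):
        # a predictor that doubles the target has |relative error| = 1
        x = np.linspace(1, 2, 50)
        phi = np.full(50, 2.0)
        errors = (phi - 2 * phi) / phi
        assert np.all(np.abs(errors) == 1.0)

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError, match="2 rows"):
            train_regressor(phi_sample([1.0], [1.0]), M0)

    def test_zero_phi_excluded(self):
        rng = np.random.default_rng(5)
        x = np.exp(rng.normal(0, 0.3, 50))
        train = phi_sample(x, np.full(50, 2.0))
        reg = train_regressor(train, M0)
        test = phi_sample(x[:10], np.r_[0.0, np.full(9, 2.0)])
        report = regression_errors(reg, test)
        assert report.n_excluded == 1
        assert len(report.errors) == 9


class TestEvaluateCombinations:
    @staticmethod
    @pytest.fixture(scope="class")
    def five_marker_samples():
        rng = np.random.default_rng(6)
        x = np.exp(rng.normal(0, 0.4, (800, 5)))
        labels = np.where(x[:, 2] > 1.0, 1, -1)
        names = [f"m{j}" for j in range(5)]
        train = delta_sample(x[:400], labels[:400], names)
        test = delta_sample(x[400:], labels[400:], names)
        return train, test

    def test_counting_and_sorting(self, five_marker_samples):
        train, test = five_marker_samples
        report = evaluate_combinations(train, test, sizes=(1, 2))
        assert len(report) == 5 + 10
        assert (report["size"].value_counts()[1], report["size"].value_counts()[2]) == (5, 10)
        assert report["auc"].is_monotonic_decreasing
        # the informative marker ranks first among singles
        singles = report[report["size"] == 1]
        assert singles.iloc[0]["markers"] == "m2"

    def test_subset_guard(self, five_marker_samples):
        train, test = five_marker_samples
        with pytest.raises(ValueError, match="subsets"):
            evaluate_combinations(train, test, sizes=(1, 2), max_subsets=3)

    def test_invalid_size_rejected(self, five_marker_samples):
        train, test = five_marker_samples
        with pytest.raises(ValueError, match="out of range"):
            evaluate_combinations(train, test, sizes=(0,))

    def test_marker_set_validation(self):
        with pytest.raises(ValueError, match="unique"):
            MarkerSet((1, 1), ("a", "a"))
        with pytest.raises(ValueError, match="at least one"):
            MarkerSet((), ())
        m = MarkerSet.from_names(["b"], ["a", "b"])
        assert m.indices == (1,)

    def test_settings_validation(self):
        with pytest.raises(ValueError):
            SVSettings(gamma=0.0)
        with pytest.raises(ValueError):
            SVSettings(epsilon=-0.1)
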