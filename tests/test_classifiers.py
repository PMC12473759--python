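import numpy as np
import pytest

from astw.classifiers_eval import (
    ClassifierSpec,
    ELMClassifier,
    compare_conditions,
    confusion,
    fit_predict,
    loto_evaluate,
)
from astw.errors import ConfigError, ContractError, StratificationError


def _blobs(rng, n=100, sep=10.0, dim=2, k=2):
    X = np.concatenate(
        [sep * i + rng.standard_normal((n, dim)) for i in range(k)], axis=0
    )
    y = np.repeat(np.arange(k), n)
    perm = rng.permutation(len(y))
    return X[perm], y[perm]


def _nearest_centroid(train_X, train_y, test_X):
    cents = np.stack([train_X[train_y == c].mean(axis=0) for c in np.unique(train_y)])
    d = ((test_X[:, None, :] - cents[None]) ** 2).sum(-1)
    return np.unique(train_y)[np.argmin(d, axis=1)]


class TestFitPredict:
    @pytest.mark.parametrize("kind", ["lda", "knn", "elm"])
    def test_well_separated_blobs_are_perfect(self, rng, kind):
        X, y = _blobs(rng)
        hold = slice(0, 40)
        spec = ClassifierSpec(kind=kind, seed=0)
        preds = fit_predict(spec, X[40:], y[40:], X[hold])
        assert np.mean(preds == y[hold]) == 1.0
        np.testing.assert_array_equal(preds, _nearest_centroid(X[40:], y[40:], X[hold]))

    def test_knn_k1_memorizes_training_set(self, rng):
        X, y = _blobs(rng, sep=2.0)
        preds = fit_predict(ClassifierSpec("knn", k=1), X, y, X)
        assert np.mean(preds == y) == 1.0

    def test_elm_is_deterministic_given_seed(self, rng):
        X, y = _blobs(rng, sep=1.0)
        p1 = fit_predict(ClassifierSpec("elm", seed=3), X, y, X)
        p2 = fit_predict(ClassifierSpec("elm", seed=3), X, y, X)
        np.testing.assert_array_equal(p1, p2)

    def test_elm_feature_permutation_invariance(self, rng):
        """Permuting features with the hidden input weights permuted alike
        leaves the hidden activations, hence predictions, unchanged."""
        X, y = _blobs(rng, dim=5, sep=3.0)
        elm = ELMClassifier(hidden=50, seed=1).fit(X, y)
        perm = rng.permutation(5)
        base = elm.predict(X)
        elm._W = elm._W[perm]
        np.testing.assert_array_equal(elm.predict(X[:, perm]), base)

    def test_missing_class_raises_stratification_error(self, rng):
        X, y = _blobs(rng, k=2)
        with pytest.raises(StratificationError):
            fit_predict(ClassifierSpec("lda"), X[y == 0], y[y == 0], X,
                        required_classes=[0, 1])

    def test_unknown_classifier_rejected(self, rng):
        X, y = _blobs(rng)
        with pytest.raises(ConfigError):
            fit_predict(ClassifierSpec("almmo"), X, y, X)

    def test_lda_shared_covariance_high_accuracy(self, rng):
        # well-separated classes with a common covariance: LDA's own model
        cov = np.array([[2.0, 0.5], [0.5, 1.0]])
        L = np.linalg.cholesky(cov)
        means = np.array([[0, 0], [6, 0], [0, 6], [6, 6]], dtype=float)
        X = np.concatenate([m + rng.standard_normal((200, 2)) @ L.T for m in means])
        y = np.repeat(np.arange(4), 200)
        preds = fit_predict(ClassifierSpec("lda"), X, y, X)
        assert np.mean(preds == y) >= 0.99


class TestLoto:
    def _trials(self, rng, n_trials=8):
        out = []
        for t in range(n_trials):
            X, y = _blobs(rng, n=30, sep=12.0, k=3)
            out.append((X, y, t))
        return out

    def test_identical_separable_trials_score_one(self, rng):
        trials = self._trials(rng)
        report = loto_evaluate(trials, ClassifierSpec("lda"), n_classes=3)
        assert report.mean_accuracy == 1.0
        assert report.std_accuracy == 0.0

    def test_fold_count_equals_trial_count(self, rng):
        report = loto_evaluate(self._trials(rng), ClassifierSpec("knn"), n_classes=3)
        assert len(report.fold_accuracies) == 8
        assert report.fold_trial_ids == list(range(8))

    def test_fold_accuracies_invariant_to_trial_order(self, rng):
        trials = self._trials(rng, 5)
        r1 = loto_evaluate(trials, ClassifierSpec("elm", seed=0), n_classes=3)
        r2 = loto_evaluate(trials[::-1], ClassifierSpec("elm", seed=0), n_classes=3)
        assert sorted(r1.fold_accuracies) == pytest.approx(sorted(r2.fold_accuracies))

    def test_duplicate_trial_ids_rejected(self, rng):
        trials = self._trials(rng, 3)
        trials[2] = (trials[2][0], trials[2][1], 0)
        with pytest.raises(ContractError):
            loto_evaluate(trials, ClassifierSpec("lda"))

    def test_single_trial_cannot_loto(self, rng):
        with pytest.raises(ContractError):
            loto_evaluate(self._trials(rng, 1), ClassifierSpec("lda"))


class TestConfusion:
    def test_perfect_predictions_are_diagonal(self):
        y = np.array([0, 1, 2, 6, 6])
        cm = confusion(y, y)
        assert cm.trace() == 5
        assert cm.sum() == 5

    def test_all_predicted_rest_is_single_column(self):
        labels = np.array([0, 1, 2, 3])
        preds = np.full(4, 6)
        cm = confusion(preds, labels)
        assert cm[:, 6].sum() == 4 and cm.sum() == 4

    def test_trace_over_total_matches_accuracy(self, rng):
        labels = rng.integers(0, 7, 50)
        preds = rng.integers(0, 7, 50)
        cm = confusion(preds, labels)
        assert cm.trace() / cm.sum() == pytest.approx(np.mean(preds == labels))


class TestRankSum:
    def test_identical_samples_give_p_one(self):
        res = compare_conditions([0.9, 0.9, 0.9], [0.9, 0.9, 0.9])
        assert res.p_value == 1.0 and not res.significant

    def test_disjoint_samples_are_significant(self):
        res = compare_conditions(np.arange(1, 11), np.arange(101, 111))
        assert res.p_value < 0.001 and res.significant

    def test_two_sided_p_is_symmetric(self, rng):
        a, b = rng.standard_normal(10), rng.standard_normal(12) + 0.5
        assert compare_conditions(a, b).p_value == pytest.approx(
            compare_conditions(b, a).p_value
        )
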