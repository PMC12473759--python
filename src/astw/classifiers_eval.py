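"""Shallow classifiers, leave-one-trial-out evaluation, and rank-sum comparisons.

The classifier roster is LDA, kNN and a single-hidden-layer extreme learning
machine (ELM): random fixed input weights, logistic hidden activation, and
ridge-regularized least-squares output weights on one-hot targets.  Further
classifiers (e.g. autonomous learning multi-model variants) can be attached
through :data:`CLASSIFIER_PLUGINS` without touching the evaluation protocol.

Evaluation is leave-one-trial-out (LOTO): each trial serves once as the test
fold while all remaining trials train the model; the reported accuracy is
the arithmetic mean over folds.  Condition comparisons use the two-sided
Wilcoxon rank-sum test at alpha = 0.05.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
from scipy import stats as sps
from scipy.special import expit
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.metrics import confusion_matrix
from sklearn.neighbors import KNeighborsClassifier

from .errors import ConfigError, ContractError, StratificationError, ValidationError

#: plugin hook: name -> factory(spec) returning an object with fit/predict
CLASSIFIER_PLUGINS: dict = {}


@dataclass(frozen=True)
class ClassifierSpec:
    """Classifier kind plus the hyperparameters that matter for it.

    kNN uses ``k`` neighbours (Euclidean metric); the ELM uses ``hidden``
    logistic units, input weights/biases uniform in [-1, 1] drawn from
    ``seed``, and ridge penalty ``ridge`` on the output weights; LDA takes
    an optional shrinkage intensity in [0, 1].
    """

    kind: str = "lda"
    k: int = 5
    hidden: int = 200
    ridge: float = 1e-3
    seed: int = 0
    shrinkage: float | None = None

    def __post_init__(self):
        if self.k < 1 or self.hidden < 1 or self.ridge <= 0:
            raise ConfigError("classifier hyperparameters must be positive")


class ELMClassifier:
    """Canonical single-hidden-layer extreme learning machine.

    Deterministic given the seed: hidden-layer weights are fixed at fit
    time and only the linear output map is solved analytically.
    """

    def __init__(self, hidden: int = 200, ridge: float = 1e-3, seed: int = 0):
        self.hidden = hidden
        self.ridge = ridge
        self.seed = seed

    def _hidden_activations(self, X):
        return expit(X @ self._W + self._b)

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        self.classes_ = np.unique(y)
        rng = np.random.default_rng(self.seed)
        d = X.shape[1]
        self._W = rng.uniform(-1.0, 1.0, size=(d, self.hidden))
        self._b = rng.uniform(-1.0, 1.0, size=self.hidden)
        H = self._hidden_activations(X)
        T = (y[:, None] == self.classes_[None, :]).astype(float)  # one-hot
        A = H.T @ H + self.ridge * np.eye(self.hidden)
        self._beta = np.linalg.solve(A, H.T @ T)
        return self

    def predict(self, X):
        scores = self._hidden_activations(np.asarray(X, dtype=float)) @ self._beta
        return self.classes_[np.argmax(scores, axis=1)]


def make_classifier(spec: ClassifierSpec):
    """Instantiate the classifier a spec describes (plugins included)."""
    if spec.kind == "lda":
        if spec.shrinkage is None:
            return LinearDiscriminantAnalysis(solver="svd")
        return LinearDiscriminantAnalysis(solver="lsqr", shrinkage=spec.shrinkage)
    if spec.kind == "knn":
        return KNeighborsClassifier(n_neighbors=spec.k)
    if spec.kind == "elm":
        return ELMClassifier(hidden=spec.hidden, ridge=spec.ridge, seed=spec.seed)
    if spec.kind in CLASSIFIER_PLUGINS:
        return CLASSIFIER_PLUGINS[spec.kind](spec)
    known = ["lda", "knn", "elm", *CLASSIFIER_PLUGINS]
    raise ConfigError(f"unknown classifier {spec.kind!r}; known: {known}")


def fit_predict(
    spec: ClassifierSpec,
    train_X: np.ndarray,
    train_y: np.ndarray,
    test_X: np.ndarray,
    required_classes=None,
) -> np.ndarray:
    """Fit the specified classifier and predict labels for the test block."""
    train_X = np.asarray(train_X, dtype=float)
    train_y = np.asarray(train_y, dtype=int)
    test_X = np.asarray(test_X, dtype=float)
    if train_X.shape[1] != test_X.shape[1]:
        raise ContractError("train/test feature dimensions differ")
    if required_classes is not None:
        missing = set(np.asarray(required_classes, dtype=int)) - set(train_y)
        if missing:
            raise StratificationError(f"classes missing from training: {sorted(missing)}")
    clf = make_classifier(spec)
    clf.fit(train_X, train_y)
    return np.asarray(clf.predict(test_X), dtype=int)


def confusion(preds: np.ndarray, labels: np.ndarray, n_classes: int = 7) -> np.ndarray:
    """Count matrix with entry (i, j) = true class i predicted as class j."""
    preds = np.asarray(preds, dtype=int)
    labels = np.asarray(labels, dtype=int)
    for arr, name in ((preds, "predictions"), (labels, "labels")):
        if arr.size and (arr.min() < 0 or arr.max() >= n_classes):
            raise ValidationError(f"{name} outside 0..{n_classes - 1}")
    return confusion_matrix(labels, preds, labels=np.arange(n_classes))


@dataclass
class EvalReport:
    """LOTO outcome: per-fold accuracies, their mean/std, summed confusion."""

    fold_accuracies: list
    confusion: np.ndarray
    condition: str = ""
    wl_ms: float = 0.0
    spec: ClassifierSpec | None = None
    fold_trial_ids: list = field(default_factory=list)

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))

    @property
    def std_accuracy(self) -> float:
        return float(np.std(self.fold_accuracies))

    def to_dict(self) -> dict:
        return {
            "condition": self.condition,
            "wl_ms": self.wl_ms,
            "classifier": None if self.spec is None else asdict(self.spec),
            "fold_trial_ids": list(self.fold_trial_ids),
            "fold_accuracies": [float(a) for a in self.fold_accuracies],
            "mean_accuracy": self.mean_accuracy,
            "std_accuracy": self.std_accuracy,
            "confusion": self.confusion.tolist(),
        }


def loto_evaluate(trials, spec: ClassifierSpec, n_classes: int = 7) -> EvalReport:
    """Leave-one-trial-out evaluation over ``[(X, y, trial_id), ...]``.

    Produces exactly one fold per trial; the summed confusion matrix pools
    all folds' test windows.
    """
    trials = list(trials)
    if len(trials) < 2:
        raise ContractError("LOTO needs at least 2 trials")
    ids = [t[2] for t in trials]
    if len(set(ids)) != len(ids):
        raise ContractError("trial ids must be unique (no train/test overlap)")
    all_classes = np.unique(np.concatenate([np.asarray(t[1]) for t in trials]))
    accs, cms, fold_ids = [], [], []
    for held in range(len(trials)):
        test_X, test_y, tid = trials[held]
        train_parts = [t for i, t in enumerate(trials) if i != held]
        train_X = np.vstack([t[0] for t in train_parts])
        train_y = np.concatenate([np.asarray(t[1]) for t in train_parts])
        preds = fit_predict(spec, train_X, train_y, test_X, required_classes=all_classes)
        test_y = np.asarray(test_y, dtype=int)
        accs.append(float(np.mean(preds == test_y)))
        cms.append(confusion(preds, test_y, n_classes=n_classes))
        fold_ids.append(tid)
    return EvalReport(
        fold_accuracies=accs,
        confusion=np.sum(cms, axis=0),
        spec=spec,
        fold_trial_ids=fold_ids,
    )


@dataclass
class ComparisonResult:
    """Two-sided Wilcoxon rank-sum outcome at a fixed alpha."""

    statistic: float
    p_value: float
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def compare_conditions(acc_a, acc_b, alpha: float = 0.05) -> ComparisonResult:
    """Wilcoxon rank-sum test between two accuracy samples.

    Fully tied samples (every value identical across both groups) carry no
    rank information; p = 1 by convention.
    """
    a = np.asarray(acc_a, dtype=float)
    b = np.asarray(acc_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ContractError("both samples must be nonempty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return ComparisonResult(statistic=0.0, p_value=1.0, alpha=alpha)
    res = sps.ranksums(a, b)
    return ComparisonResult(statistic=float(res.statistic), p_value=float(res.pvalue), alpha=alpha)
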