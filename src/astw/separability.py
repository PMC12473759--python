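"""Class separability index (SI) over a labelled feature set.

For each class j the *most conflicting* class C_j is the class at minimum
half-Mahalanobis distance

    d(j, k) = 1/2 * sqrt( (m_j - m_k)^T Sigma^{-1} (m_j - m_k) ),
    Sigma   = (Sigma_j + Sigma_k) / 2,

where m and Sigma are the per-class sample mean and (unbiased) covariance.
The SI is the mean over classes of d(j, C_j).  Higher SI means the classes
are further apart relative to their spread, i.e. a better feature mapping.

Covariance inversion is regularized by adding ``ridge * trace(Sigma)/dim``
to the diagonal, which keeps the index defined when the feature dimension
exceeds the per-class sample count (dimension 84 vs short trials).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .errors import ContractError, InsufficientDataError, NumericError

DEFAULT_RIDGE = 1e-6


@dataclass
class ClassStats:
    """Per-class sample means, covariances and counts."""

    means: dict
    covs: dict
    counts: dict

    @property
    def classes(self):
        return sorted(self.means)


@dataclass
class SiResult:
    """SI value with each class's conflicting class and distance."""

    si: float
    conflicts: dict = field(default_factory=dict)  # class -> (conflict class, distance)


def class_stats(features: np.ndarray, labels: np.ndarray) -> ClassStats:
    """Unbiased per-class means and covariances; every class needs >= 2 samples."""
    X = np.atleast_2d(np.asarray(features, dtype=float))
    y = np.asarray(labels, dtype=int)
    if X.shape[0] != y.shape[0]:
        raise ContractError("features and labels must align")
    means, covs, counts = {}, {}, {}
    for cls in np.unique(y):
        Xc = X[y == cls]
        if Xc.shape[0] < 2:
            raise InsufficientDataError(
                f"class {cls} has {Xc.shape[0]} sample(s); covariance needs >= 2"
            )
        means[int(cls)] = Xc.mean(axis=0)
        covs[int(cls)] = np.cov(Xc, rowvar=False).reshape(X.shape[1], X.shape[1])
        counts[int(cls)] = Xc.shape[0]
    return ClassStats(means=means, covs=covs, counts=counts)


def _regularize(sigma: np.ndarray, ridge: float) -> np.ndarray:
    dim = sigma.shape[0]
    scale = np.trace(sigma) / dim
    if scale <= 0:
        scale = 1.0
    return sigma + ridge * scale * np.eye(dim)


def pairwise_class_distance(
    j: int, k: int, stats: ClassStats, ridge: float = DEFAULT_RIDGE
) -> float:
    """Half-Mahalanobis distance between classes j and k with pooled covariance."""
    dm = stats.means[j] - stats.means[k]
    sigma = _regularize((stats.covs[j] + stats.covs[k]) / 2.0, ridge)
    try:
        sol = linalg.solve(sigma, dm, assume_a="sym")
    except linalg.LinAlgError as exc:  # pragma: no cover - pathological input
        raise NumericError(f"pooled covariance not invertible: {exc}") from exc
    q = float(dm @ sol)
    if not np.isfinite(q) or q < -1e-9:
        raise NumericError("Mahalanobis quadratic form is not finite and nonnegative")
    return 0.5 * np.sqrt(max(q, 0.0))


def separability_index(
    features: np.ndarray, labels: np.ndarray, ridge: float = DEFAULT_RIDGE
) -> SiResult:
    """SI = mean over classes of the distance to the most conflicting class.

    Ties in the argmin are broken toward the smaller class index.
    """
    stats = class_stats(features, labels)
    classes = stats.classes
    if len(classes) < 2:
        raise InsufficientDataError("SI needs at least 2 classes")
    conflicts = {}
    for j in classes:
        best = None
        for k in classes:
            if k == j:
                continue
            d = pairwise_class_distance(j, k, stats, ridge)
            if best is None or d < best[1] - 1e-15:
                best = (k, d)
        conflicts[j] = best
    si = float(np.mean([d for _, d in conflicts.values()]))
    return SiResult(si=si, conflicts=conflicts)
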