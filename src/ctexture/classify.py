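"""Distance measures and pattern classification.

Per-sample classification uses the Euclidean distance between z-scored
feature vectors and a k-nearest-neighbor majority vote (k = 3 by default).
Group-level assignment uses the Bhattacharyya distance between Gaussian
class models,

    D_B = 1/8 (m_i - m_j)^T [(C_i + C_j)/2]^{-1} (m_i - m_j)
        + 1/2 ln( |(C_i + C_j)/2| / sqrt(|C_i| |C_j|) ),

which combines a Mahalanobis-like mean-separation term with a
covariance-overlap term. A set of query vectors is fitted with its own mean
and covariance and assigned to the trained class at minimum Bhattacharyya
distance — the class-separability route used when whole sample populations,
rather than single windows, are compared.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .patterns import FeatureVector, LabeledPatternSet

__all__ = [
    "ClassModel",
    "KnnConfig",
    "euclidean_distance",
    "bhattacharyya_distance",
    "fit_class_model",
    "fit_class_models",
    "knn_classify",
    "separability_classify",
]

#: Ridge scale for covariance regularization: eps = RIDGE * trace(C)/dim is
#: added to the diagonal before inversion, since 6 features can exceed the
#: sample count of a small class.
RIDGE = 1e-6


@dataclass(frozen=True)
class ClassModel:
    """Gaussian summary of one class: mean vector, covariance matrix, count."""

    label: str
    mean_vec: np.ndarray
    cov: np.ndarray
    count: int

    def __post_init__(self) -> None:
        m = np.asarray(self.mean_vec, float)
        c = np.asarray(self.cov, float)
        if c.shape != (m.size, m.size):
            raise ValueError(f"covariance shape {c.shape} does not match mean {m.shape}")
        if not np.allclose(c, c.T):
            raise ValueError("covariance must be symmetric")
        object.__setattr__(self, "mean_vec", m)
        object.__setattr__(self, "cov", c)


@dataclass(frozen=True)
class KnnConfig:
    """Neighbor count and distance choice for per-sample classification."""

    k: int = 3
    distance: str = "euclidean"

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.distance not in {"euclidean", "bhattacharyya"}:
            raise ValueError(f"unknown distance {self.distance!r}")


def _as_vector(v) -> np.ndarray:
    return v.to_array() if isinstance(v, FeatureVector) else np.asarray(v, float)


def euclidean_distance(f, q) -> float:
    """Euclidean distance between two equal-length feature vectors."""
    f, q = _as_vector(f), _as_vector(q)
    if f.shape != q.shape:
        raise ValueError(f"length mismatch: {f.shape} vs {q.shape}")
    # left-to-right accumulation: bit-for-bit the textbook definition
    total = 0.0
    for a, b in zip(f.ravel(), q.ravel()):
        total += (a - b) ** 2
    return math.sqrt(total)


def _regularized(c: np.ndarray) -> np.ndarray:
    # ridge only when the covariance is singular or near-singular, so
    # well-posed models keep their exact closed-form distances
    w = np.linalg.eigvalsh(c)
    if w[0] > 1e-10 * max(w[-1], 1.0):
        return c
    dim = c.shape[0]
    eps = RIDGE * np.trace(c) / dim
    if eps <= 0:
        eps = RIDGE
    return c + eps * np.eye(dim)


def bhattacharyya_distance(a: ClassModel, b: ClassModel) -> float:
    """Bhattacharyya distance between two Gaussian class models.

    Symmetric, non-negative, and 0 for identical models. Covariances are
    ridge-regularized before inversion; a still-singular average covariance
    raises ``np.linalg.LinAlgError`` with a diagnostic.
    """
    ca, cb = _regularized(a.cov), _regularized(b.cov)
    avg = (ca + cb) / 2.0
    dm = a.mean_vec - b.mean_vec
    try:
        sol = np.linalg.solve(avg, dm)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - ridge prevents this
        raise np.linalg.LinAlgError(
            f"singular averaged covariance for classes {a.label!r}/{b.label!r}"
        ) from exc
    term_mean = 0.125 * float(dm @ sol)
    sign, logdet_avg = np.linalg.slogdet(avg)
    if sign <= 0:
        raise np.linalg.LinAlgError(
            f"non-positive-definite averaged covariance for {a.label!r}/{b.label!r}"
        )
    logdet_a = np.linalg.slogdet(ca)[1]
    logdet_b = np.linalg.slogdet(cb)[1]
    term_cov = 0.5 * (logdet_avg - 0.5 * (logdet_a + logdet_b))
    return term_mean + term_cov


def fit_class_model(label: str, vectors: np.ndarray) -> ClassModel:
    """Estimate mean vector and (population) covariance for one class."""
    mat = np.atleast_2d(np.asarray(vectors, float))
    if mat.shape[0] < 2:
        raise ValueError(f"class {label!r} needs >= 2 samples to fit a model")
    mean = mat.mean(axis=0)
    dev = mat - mean
    cov = dev.T @ dev / mat.shape[0]
    return ClassModel(label=label, mean_vec=mean, cov=cov, count=mat.shape[0])


def fit_class_models(train: LabeledPatternSet) -> list[ClassModel]:
    """One :class:`ClassModel` per class present in the training set."""
    return [fit_class_model(c, mat) for c, mat in train.by_class().items()]


def knn_classify(
    test, train: LabeledPatternSet, cfg: KnnConfig = KnnConfig()
) -> str:
    """Majority label among the k nearest training vectors (Euclidean).

    Ties — equal votes among classes — are broken by the smallest mean
    distance to the query among the tied classes, then by vocabulary order;
    the result is deterministic and independent of training-set order.
    """
    if len(train) == 0:
        raise ValueError("empty training set")
    if cfg.k > len(train):
        raise ValueError(f"k={cfg.k} exceeds training size {len(train)}")
    if cfg.distance != "euclidean":
        raise ValueError(
            "per-sample k-NN uses the Euclidean distance; Bhattacharyya "
            "operates on groups via separability_classify"
        )
    q = _as_vector(test)
    mat = train.to_matrix()
    d = np.linalg.norm(mat - q, axis=1)
    # stable argsort + label tie-break keeps the result order-independent
    order = np.argsort(d, kind="stable")
    kth = d[order[cfg.k - 1]]
    in_k = np.flatnonzero(d <= kth)  # include distance ties at the boundary
    labels = np.asarray(train.labels)[in_k]
    vocab_rank = {c: i for i, c in enumerate(train.class_vocabulary)}
    classes, votes = np.unique(labels, return_counts=True)
    best_votes = votes.max()
    tied = [c for c, v in zip(classes, votes) if v == best_votes]
    if len(tied) > 1:
        mean_d = {c: d[in_k][labels == c].mean() for c in tied}
        tied.sort(key=lambda c: (mean_d[c], vocab_rank[c]))
    return str(tied[0])


def separability_classify(test_group, models: list[ClassModel]) -> str:
    """Assign a group of feature vectors to the nearest class distribution.

    Fits a Gaussian model to ``test_group`` (>= 2 vectors) and returns the
    label of the trained :class:`ClassModel` at minimum Bhattacharyya
    distance. Ties break by model list order.
    """
    if not models:
        raise ValueError("no trained class models")
    mat = np.vstack([_as_vector(v) for v in test_group])
    if mat.shape[0] < 2:
        raise ValueError("need >= 2 vectors to estimate a group model")
    group = fit_class_model("__query__", mat)
    dists = [bhattacharyya_distance(group, m) for m in models]
    return models[int(np.argmin(dists))].label
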