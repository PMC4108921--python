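"""Feature vectors and labeled pattern collections.

The six-element descriptor of a window — mean, variance, skewness, excess
kurtosis, GLCM entropy and box-counting fractal dimension — is the common
currency between feature extraction, normalization, classification and the
ROI search, so its container lives here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FEATURE_NAMES",
    "DEFAULT_CLASS_ORDER",
    "FeatureVector",
    "LabeledPatternSet",
]

FEATURE_NAMES: tuple[str, ...] = (
    "mean",
    "variance",
    "skewness",
    "excess_kurtosis",
    "glcm_entropy",
    "fractal_dim",
)

#: Reporting order of the trained attenuation-pattern classes. ``benign_gray``
#: and ``benign_control_like`` are trained as separate sub-patterns but merged
#: into ``benign`` in confusion matrices (see evaluation module).
DEFAULT_CLASS_ORDER: tuple[str, ...] = (
    "white",
    "gray",
    "water_halo",
    "fat_halo",
    "black",
    "ischemia",
    "benign",
    "control",
)


@dataclass(frozen=True)
class FeatureVector:
    """Six texture descriptors of one grayscale window.

    ``mean`` is in intensity units, ``variance`` in intensity squared,
    ``glcm_entropy`` in nats; the remaining three are dimensionless.
    ``degenerate`` flags a zero-variance window whose shape moments are
    undefined and were recorded as 0.
    """

    mean: float
    variance: float
    skewness: float
    excess_kurtosis: float
    glcm_entropy: float
    fractal_dim: float
    degenerate: bool = field(default=False, compare=False)
    debug: dict = field(default_factory=dict, compare=False, repr=False)

    def to_array(self) -> np.ndarray:
        return np.array(
            [
                self.mean,
                self.variance,
                self.skewness,
                self.excess_kurtosis,
                self.glcm_entropy,
                self.fractal_dim,
            ],
            dtype=np.float64,
        )

    @classmethod
    def from_array(cls, arr: np.ndarray, degenerate: bool = False) -> "FeatureVector":
        arr = np.asarray(arr, dtype=np.float64)
        if arr.shape != (len(FEATURE_NAMES),):
            raise ValueError(f"expected {len(FEATURE_NAMES)} features, got {arr.shape}")
        return cls(*map(float, arr), degenerate=degenerate)


class LabeledPatternSet:
    """Parallel lists of feature vectors and class labels.

    Parameters
    ----------
    vectors
        Sequence of :class:`FeatureVector` (or length-6 arrays).
    labels
        Parallel sequence of class identifiers.
    class_vocabulary
        Ordered class list; defaults to the distinct labels in order of first
        appearance. Every label must be in the vocabulary.
    """

    def __init__(self, vectors, labels, class_vocabulary=None):
        vecs = [
            v if isinstance(v, FeatureVector) else FeatureVector.from_array(v)
            for v in vectors
        ]
        labels = list(labels)
        if len(vecs) != len(labels):
            raise ValueError(
                f"{len(vecs)} vectors but {len(labels)} labels"
            )
        if class_vocabulary is None:
            class_vocabulary = list(dict.fromkeys(labels))
        unknown = set(labels) - set(class_vocabulary)
        if unknown:
            raise ValueError(f"labels outside vocabulary: {sorted(unknown)}")
        self.vectors: list[FeatureVector] = vecs
        self.labels: list[str] = labels
        self.class_vocabulary: list[str] = list(class_vocabulary)

    def __len__(self) -> int:
        return len(self.vectors)

    def to_matrix(self) -> np.ndarray:
        """Stack the feature vectors into an ``(n, 6)`` float matrix."""
        if not self.vectors:
            return np.empty((0, len(FEATURE_NAMES)))
        return np.vstack([v.to_array() for v in self.vectors])

    def subset(self, indices) -> "LabeledPatternSet":
        return LabeledPatternSet(
            [self.vectors[i] for i in indices],
            [self.labels[i] for i in indices],
            self.class_vocabulary,
        )

    def by_class(self) -> dict[str, np.ndarray]:
        """Feature matrix per class, in vocabulary order (present classes only)."""
        mat = self.to_matrix()
        lab = np.asarray(self.labels)
        return {
            c: mat[lab == c]
            for c in self.class_vocabulary
            if (lab == c).any()
        }
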