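"""Windowed texture features: histogram moments, GLCM entropy, fractal dimension.

All moments use the population convention (divisor ``N``): the mean
``m = (1/N) sum x_i``, the variance ``sigma^2 = (1/N) sum (x_i - m)^2``, the
coefficient of skewness ``g1 = (1/N) sum ((x_i - m)/sigma)^3`` and kurtosis in
the *excess* convention ``g2 = (1/N) sum ((x_i - m)/sigma)^4 - 3``, so a
normal gray-level distribution scores 0 for both shape coefficients.

The gray-level co-occurrence matrix (GLCM) counts ordered pixel pairs at a
fixed (row, col) displacement after quantizing intensities to ``L`` levels;
its entropy ``H = -sum a_pq ln a_pq`` (nats, with ``0 ln 0 = 0``) is the only
GLCM descriptor used. The fractal dimension is the classic box-counting
dimension of a binarized window: minus the least-squares slope of
``log n(r)`` against ``log r`` over a dyadic ladder of box sizes ``r``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .image import GrayImage
from .patterns import FEATURE_NAMES, FeatureVector, LabeledPatternSet

__all__ = [
    "DegenerateMomentError",
    "GlcmSpec",
    "Glcm",
    "BoxCountCurve",
    "FdConfig",
    "NormalizationModel",
    "intensity_mean",
    "intensity_variance",
    "skewness",
    "excess_kurtosis",
    "quantize",
    "compute_glcm",
    "glcm_entropy",
    "box_count",
    "dyadic_box_sizes",
    "fractal_dimension",
    "extract_features",
    "fit_normalization",
    "apply_normalization",
]


class DegenerateMomentError(ValueError):
    """Raised when a shape moment is requested for a zero-variance window."""


# ---------------------------------------------------------------------------
# summary statistics


def _values(img) -> np.ndarray:
    px = img.pixels if isinstance(img, GrayImage) else np.asarray(img)
    if px.size == 0:
        raise ValueError("empty image")
    return px.astype(np.float64).ravel()


def intensity_mean(img) -> float:
    """Arithmetic average gray level."""
    return float(_values(img).mean())


def intensity_variance(img) -> float:
    """Population variance of the gray levels (divisor N)."""
    return float(_values(img).var())


def skewness(img) -> float:
    """Coefficient of skewness g1 of the gray-level histogram."""
    x = _values(img)
    sigma = x.std()
    if sigma == 0:
        raise DegenerateMomentError("skewness undefined for constant image")
    return float(np.mean(((x - x.mean()) / sigma) ** 3))


def excess_kurtosis(img) -> float:
    """Excess kurtosis (raw population kurtosis minus 3) of the histogram."""
    x = _values(img)
    sigma = x.std()
    if sigma == 0:
        raise DegenerateMomentError("kurtosis undefined for constant image")
    return float(np.mean(((x - x.mean()) / sigma) ** 4) - 3.0)


# ---------------------------------------------------------------------------
# gray-level co-occurrence matrix


@dataclass(frozen=True)
class GlcmSpec:
    """Displacement and quantization of a co-occurrence matrix.

    ``offset`` is a (d_r, d_c) pixel displacement with rows increasing
    downward; the default ``(1, 1)`` pairs each pixel with its neighbor one
    to the right and one down. ``levels`` is the quantized gray-level count
    L; intensities are uniformly binned from the image bit range to L bins.
    """

    offset: tuple[int, int] = (1, 1)
    levels: int = 32

    def __post_init__(self) -> None:
        if tuple(self.offset) == (0, 0):
            raise ValueError("GLCM offset must be nonzero")
        if self.levels < 2:
            raise ValueError("GLCM needs at least 2 levels")


@dataclass(frozen=True)
class Glcm:
    """Co-occurrence counts c_pq, probabilities a_pq and the pair total N(theta)."""

    counts: np.ndarray
    probabilities: np.ndarray
    pair_total: int


def quantize(img: GrayImage, levels: int) -> np.ndarray:
    """Uniformly bin the image bit range ``[0, img.levels)`` into ``levels`` bins."""
    q = (img.pixels.astype(np.int64) * levels) // img.levels
    return np.minimum(q, levels - 1)


def compute_glcm(img: GrayImage, spec: GlcmSpec = GlcmSpec()) -> Glcm:
    """Accumulate the asymmetric (ordered-pair) GLCM at ``spec.offset``.

    ``counts[p, q]`` is the number of pixel pairs whose first member has
    quantized level p and whose second member — displaced by (d_r, d_c) —
    has level q. Probabilities are counts normalized by the pair total.
    """
    dr, dc = spec.offset
    h, w = img.shape
    if h <= abs(dr) or w <= abs(dc):
        raise ValueError(
            f"image {img.shape} has no pixel pairs at offset ({dr}, {dc})"
        )
    q = quantize(img, spec.levels)
    # slice the 'first' and 'second' members of every valid pair
    r0 = slice(max(0, -dr), h - max(0, dr))
    c0 = slice(max(0, -dc), w - max(0, dc))
    r1 = slice(max(0, dr), h + min(0, dr))
    c1 = slice(max(0, dc), w + min(0, dc))
    first = q[r0, c0].ravel()
    second = q[r1, c1].ravel()
    L = spec.levels
    counts = np.bincount(first * L + second, minlength=L * L).reshape(L, L)
    total = int(counts.sum())
    probs = counts / total if total > 0 else counts.astype(np.float64)
    return Glcm(counts=counts, probabilities=probs.astype(np.float64), pair_total=total)


def glcm_entropy(g: Glcm) -> float:
    """Shannon entropy -sum a_pq ln a_pq in nats; empty cells contribute 0."""
    p = g.probabilities[g.probabilities > 0]
    return float(-(p * np.log(p)).sum()) if p.size else 0.0


# ---------------------------------------------------------------------------
# box-counting fractal dimension


@dataclass(frozen=True)
class BoxCountCurve:
    """The (r, n(r)) occupancy curve and the straight-line fit through its logs."""

    box_sizes: tuple[int, ...]
    box_counts: tuple[int, ...]
    slope_fit: float
    fit_residual: float


@dataclass(frozen=True)
class FdConfig:
    """Binarization and box-ladder settings for the fractal dimension.

    ``threshold`` selects the foreground rule applied to a grayscale window:
    ``"mean"`` (default) thresholds at the window's mean intensity, ``"otsu"``
    uses Otsu's method, and a number is used as a fixed cutoff. Pixels
    strictly above the cutoff are foreground. ``box_sizes`` defaults to the
    dyadic ladder 1, 2, 4, ... up to half the shorter window side, with the
    counting grid anchored at the window origin.
    """

    threshold: str | float = "mean"
    box_sizes: tuple[int, ...] | None = None


def box_count(foreground: np.ndarray, r: int) -> int:
    """Number of r x r grid cells (grid anchored at the origin) touching foreground."""
    if r < 1:
        raise ValueError("box size must be >= 1")
    fg = np.asarray(foreground, dtype=bool)
    h, w = fg.shape
    nr, nc = -(-h // r), -(-w // r)
    padded = np.zeros((nr * r, nc * r), dtype=bool)
    padded[:h, :w] = fg
    occupied = padded.reshape(nr, r, nc, r).any(axis=(1, 3))
    return int(occupied.sum())


def dyadic_box_sizes(shape: tuple[int, int]) -> tuple[int, ...]:
    """Sizes 1, 2, 4, ... up to half the shorter side (at least three sizes)."""
    limit = max(min(shape) // 2, 4)
    sizes = []
    r = 1
    while r <= limit:
        sizes.append(r)
        r *= 2
    return tuple(sizes)


def fractal_dimension(
    foreground: np.ndarray, sizes=None
) -> tuple[float, BoxCountCurve]:
    """Box-counting dimension of a binary mask.

    Fits log n(r) against log r by least squares over the given box sizes and
    returns minus the slope together with the raw curve for inspection.
    """
    fg = np.asarray(foreground, dtype=bool)
    if not fg.any():
        raise ValueError("fractal dimension undefined for empty foreground")
    if sizes is None:
        sizes = dyadic_box_sizes(fg.shape)
    sizes = tuple(int(r) for r in sizes)
    if len(sizes) < 3:
        raise ValueError("need at least 3 box sizes for a slope fit")
    counts = tuple(box_count(fg, r) for r in sizes)
    logr = np.log(sizes)
    logn = np.log(counts)
    slope, intercept = np.polyfit(logr, logn, 1)
    resid = float(np.sqrt(np.mean((slope * logr + intercept - logn) ** 2)))
    curve = BoxCountCurve(sizes, counts, slope_fit=float(-slope), fit_residual=resid)
    return float(-slope), curve


def _binarize(img: GrayImage, cfg: FdConfig) -> np.ndarray:
    if isinstance(cfg.threshold, str):
        if cfg.threshold == "mean":
            cut = img.pixels.mean()
        elif cfg.threshold == "otsu":
            from skimage.filters import threshold_otsu

            cut = threshold_otsu(img.pixels)
        else:
            raise ValueError(f"unknown threshold rule {cfg.threshold!r}")
    else:
        cut = float(cfg.threshold)
    return img.pixels > cut


# ---------------------------------------------------------------------------
# composition


def extract_features(
    img: GrayImage,
    spec: GlcmSpec = GlcmSpec(),
    fd_config: FdConfig = FdConfig(),
) -> FeatureVector:
    """Compute the six-element feature vector of one window.

    A zero-variance window has undefined shape moments; they are recorded as
    0 and the vector is flagged ``degenerate`` so a whole-image scan is not
    aborted by one flat window. Raw (non-excess) kurtosis and the box-count
    curve are kept in ``debug``.
    """
    m = intensity_mean(img)
    var = intensity_variance(img)
    degenerate = var == 0.0
    if degenerate:
        g1, g2 = 0.0, 0.0
        raw_kurt = float("nan")
    else:
        g1 = skewness(img)
        g2 = excess_kurtosis(img)
        raw_kurt = g2 + 3.0
    entropy = glcm_entropy(compute_glcm(img, spec))
    mask = _binarize(img, fd_config)
    if mask.any() and not mask.all():
        fd, curve = fractal_dimension(mask, fd_config.box_sizes)
    else:
        # flat or fully-foreground window: the occupied set is the whole
        # (or empty) plane; report the plane dimension of the non-empty case
        fd = 2.0 if mask.any() else 0.0
        curve = None
    return FeatureVector(
        mean=m,
        variance=var,
        skewness=g1,
        excess_kurtosis=g2,
        glcm_entropy=entropy,
        fractal_dim=fd,
        degenerate=degenerate,
        debug={"raw_kurtosis": raw_kurt, "box_curve": curve},
    )


# ---------------------------------------------------------------------------
# z-score normalization


@dataclass(frozen=True)
class NormalizationModel:
    """Per-feature mean and standard deviation estimated from a training set."""

    mean: np.ndarray
    std: np.ndarray

    def to_dict(self) -> dict:
        return {"mean": self.mean.tolist(), "std": self.std.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "NormalizationModel":
        return cls(np.asarray(d["mean"], float), np.asarray(d["std"], float))


def fit_normalization(train) -> NormalizationModel:
    """Estimate per-feature mean and standard deviation from a training set.

    ``train`` may be a :class:`LabeledPatternSet` or an ``(n, 6)`` matrix.
    A feature with zero spread cannot be scaled; its std is recorded as 0 and
    :func:`apply_normalization` maps it to 0 with a warning.
    """
    mat = train.to_matrix() if isinstance(train, LabeledPatternSet) else np.asarray(train, float)
    if mat.ndim != 2 or mat.shape[0] < 2:
        raise ValueError("need at least 2 training vectors to fit normalization")
    return NormalizationModel(mean=mat.mean(axis=0), std=mat.std(axis=0))


def apply_normalization(model: NormalizationModel, vec) -> np.ndarray:
    """Map features to z-scores ``(f - mu_f) / sigma_f``; zero-spread features -> 0.

    Accepts a :class:`FeatureVector`, a length-6 array or an ``(n, 6)`` matrix
    and returns an array of the same leading shape.
    """
    arr = vec.to_array() if isinstance(vec, FeatureVector) else np.asarray(vec, float)
    zero = model.std == 0
    if zero.any():
        names = [FEATURE_NAMES[i] for i in np.flatnonzero(zero)]
        warnings.warn(f"zero-spread features mapped to 0: {names}")
    safe = np.where(zero, 1.0, model.std)
    out = (arr - model.mean) / safe
    if arr.ndim == 1:
        out[zero] = 0.0
    else:
        out[:, zero] = 0.0
    return out
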