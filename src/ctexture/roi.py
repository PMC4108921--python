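"""Forward expanding-window search for regions of interest.

A scan window of the average trained-pattern size starts at the top-left
corner and moves left-to-right, top-to-bottom. Each window's feature vector
is z-scored and compared against every trained pattern; the similarity score
is the per-feature relative error, aggregated over the six features. A
window scoring at or below the threshold is retained as a detection and
spawns candidate windows to its right, below and diagonal, each re-scored
independently, recursing to a bounded expansion depth. This proposes bowel
regions worth inspecting without requiring an intestinal segmentation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .features import FdConfig, GlcmSpec, NormalizationModel, apply_normalization, extract_features
from .image import GrayImage
from .patterns import LabeledPatternSet

__all__ = [
    "Window",
    "SearchConfig",
    "Detection",
    "relative_error",
    "relative_error_score",
    "average_window_size",
    "match_window",
    "forward_search",
    "merge_detections",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True, order=True)
class Window:
    """Axis-aligned rectangle: 0-based top-left (row, col) and size in pixels."""

    row: int
    col: int
    height: int
    width: int

    def __post_init__(self) -> None:
        if self.height < 1 or self.width < 1:
            raise ValueError("window size must be >= 1 pixel")
        if self.row < 0 or self.col < 0:
            raise ValueError("window position must be non-negative")

    def inside(self, shape: tuple[int, int]) -> bool:
        return self.row + self.height <= shape[0] and self.col + self.width <= shape[1]

    def overlap_fraction(self, other: "Window") -> float:
        """Fraction of *this* window's area covered by ``other``."""
        dr = min(self.row + self.height, other.row + other.height) - max(self.row, other.row)
        dc = min(self.col + self.width, other.col + other.width) - max(self.col, other.col)
        if dr <= 0 or dc <= 0:
            return 0.0
        return dr * dc / (self.height * self.width)


@dataclass(frozen=True)
class SearchConfig:
    """Scan and acceptance settings for the forward search.

    ``threshold`` is the relative-error percentage below which a window is
    retained (default 20%). ``stride`` of ``None`` means one full window per
    step — the window-quantized motion of the primary scan — and may be
    lowered to 1 pixel for dense scanning. ``expand`` chooses between
    spawning same-size neighbor windows (``"neighbors"``, default) and
    growing the window in place (``"grow"``); ``max_expansions`` caps the
    recursion depth. ``aggregate`` picks the per-feature reduction of the
    relative error (``"mean"`` default, ``"max"`` stricter).
    """

    threshold: float = 20.0
    stride: int | None = None
    max_expansions: int = 3
    window_size: tuple[int, int] | None = None
    expand: str = "neighbors"
    aggregate: str = "mean"
    score_on: str = "raw"

    def __post_init__(self) -> None:
        if self.threshold < 0:
            raise ValueError("threshold must be >= 0")
        if self.stride is not None and self.stride < 1:
            raise ValueError("stride must be >= 1 pixel")
        if self.max_expansions < 0:
            raise ValueError("max_expansions must be >= 0")
        if self.expand not in {"neighbors", "grow"}:
            raise ValueError(f"unknown expansion mode {self.expand!r}")
        if self.aggregate not in {"mean", "max"}:
            raise ValueError(f"unknown aggregate {self.aggregate!r}")
        if self.score_on not in {"raw", "zscore"}:
            raise ValueError(f"unknown score_on {self.score_on!r}")


@dataclass(frozen=True)
class Detection:
    """A retained window, its best-matching class and its score (lower = better)."""

    window: Window
    matched_class: str
    score: float
    euclidean: float = float("nan")


def relative_error(test_val: float, labeled_val: float) -> float:
    """Symmetric relative error between two feature values, in percent.

    Defined as ``|a - b| / max(|a|, |b|) * 100``, which for two values of the
    same sign equals ``(1 - Fhat/F) * 100`` with F the larger and Fhat the
    smaller value — the swap that makes the measure symmetric. Two zeros are
    a perfect match (0); one zero against a nonzero value scores 100.
    """
    a, b = float(test_val), float(labeled_val)
    denom = max(abs(a), abs(b))
    if denom == 0.0:
        return 0.0
    return abs(a - b) / denom * 100.0


def relative_error_score(test_vec, labeled_vec, aggregate: str = "mean") -> float:
    """Aggregate per-feature relative error between two feature vectors."""
    t = np.asarray(test_vec, float)
    l = np.asarray(labeled_vec, float)
    if t.shape != l.shape:
        raise ValueError(f"length mismatch: {t.shape} vs {l.shape}")
    errs = [relative_error(a, b) for a, b in zip(t, l)]
    return float(np.max(errs) if aggregate == "max" else np.mean(errs))


def average_window_size(sizes) -> tuple[int, int]:
    """Component-wise mean of (height, width) pairs, rounded to nearest pixel."""
    sizes = list(sizes)
    if not sizes:
        raise ValueError("no pattern sizes given")
    h = round(float(np.mean([s[0] for s in sizes])))
    w = round(float(np.mean([s[1] for s in sizes])))
    return int(h), int(w)


def match_window(
    img: GrayImage,
    w: Window,
    trained: LabeledPatternSet,
    cfg: SearchConfig,
    norm: NormalizationModel,
    glcm_spec: GlcmSpec = GlcmSpec(),
    fd_config: FdConfig = FdConfig(),
):
    """Score one window against every trained pattern.

    Returns ``(label, score, euclidean)`` for the minimum-score trained
    pattern if the score is within the threshold, else ``None``. The score
    is the aggregated per-feature relative error on raw feature values —
    relative error is scale-free per feature, and z-scored values cross
    zero where a ratio-based error loses meaning (``cfg.score_on="zscore"``
    restores the z-scored variant). The z-scored Euclidean distance to the
    best pattern is returned as a diagnostic. Degenerate (zero-variance)
    windows never match; the reason is logged.
    """
    if not w.inside(img.shape):
        raise ValueError(f"window {w} exceeds image bounds {img.shape}")
    fv = extract_features(img.crop(w.row, w.col, w.height, w.width), glcm_spec, fd_config)
    if fv.degenerate:
        logger.debug("window %s degenerate (zero variance); no match", w)
        return None
    raw = fv.to_array()
    mat = trained.to_matrix()
    if cfg.score_on == "raw":
        scores = np.array([relative_error_score(raw, row, cfg.aggregate) for row in mat])
    else:
        z = apply_normalization(norm, raw)
        zmat = apply_normalization(norm, mat)
        scores = np.array([relative_error_score(z, row, cfg.aggregate) for row in zmat])
    best = int(np.argmin(scores))
    if scores[best] > cfg.threshold:
        return None
    eucl = float(
        np.linalg.norm(apply_normalization(norm, raw) - apply_normalization(norm, mat[best]))
    )
    return trained.labels[best], float(scores[best]), eucl


def _neighbors(w: Window, mode: str) -> list[Window]:
    if mode == "neighbors":
        return [
            Window(w.row, w.col + w.width, w.height, w.width),
            Window(w.row + w.height, w.col, w.height, w.width),
            Window(w.row + w.height, w.col + w.width, w.height, w.width),
        ]
    # grow mode: enlarge in place toward right / below / diagonal
    return [
        Window(w.row, w.col, w.height, w.width * 2),
        Window(w.row, w.col, w.height * 2, w.width),
        Window(w.row, w.col, w.height * 2, w.width * 2),
    ]


def forward_search(
    img: GrayImage,
    trained: LabeledPatternSet,
    cfg: SearchConfig = SearchConfig(),
    norm: NormalizationModel | None = None,
    glcm_spec: GlcmSpec = GlcmSpec(),
    fd_config: FdConfig = FdConfig(),
    pattern_sizes=None,
) -> list[Detection]:
    """Raster-scan the image and expand around every match.

    ``cfg.window_size`` defaults to :func:`average_window_size` of
    ``pattern_sizes`` (required if neither is given). ``norm`` defaults to a
    z-scoring model fitted on the trained patterns themselves. Detections are
    deduplicated by window position; the list is sorted by (row, col) and is
    deterministic for fixed inputs.
    """
    from .features import fit_normalization

    if cfg.window_size is not None:
        wh, ww = cfg.window_size
    elif pattern_sizes:
        wh, ww = average_window_size(pattern_sizes)
    else:
        raise ValueError("either cfg.window_size or pattern_sizes is required")
    if norm is None:
        norm = fit_normalization(trained)
    h, w = img.shape
    if h < wh or w < ww:
        warnings.warn(f"image {img.shape} smaller than scan window ({wh}, {ww})")
        return []

    sr = cfg.stride if cfg.stride is not None else wh
    sc = cfg.stride if cfg.stride is not None else ww
    seen: set[Window] = set()
    detections: dict[Window, Detection] = {}

    def visit(win: Window, depth: int) -> None:
        if win in seen or not win.inside(img.shape):
            return
        seen.add(win)
        hit = match_window(img, win, trained, cfg, norm, glcm_spec, fd_config)
        if hit is None:
            return
        label, score, eucl = hit
        detections[win] = Detection(win, label, score, eucl)
        if depth < cfg.max_expansions:
            for nb in _neighbors(win, cfg.expand):
                visit(nb, depth + 1)

    for r in range(0, h - wh + 1, sr):
        for c in range(0, w - ww + 1, sc):
            visit(Window(r, c, wh, ww), 0)
    return sorted(detections.values(), key=lambda d: d.window)


def merge_detections(detections: list[Detection]) -> list[Detection]:
    """Merge overlapping same-class detections into union bounding boxes.

    Reporting convenience: adjacent small windows of one class collapse to a
    single box carrying the best (lowest) score. The raw list is untouched.
    """
    by_class: dict[str, list[Detection]] = {}
    for d in detections:
        by_class.setdefault(d.matched_class, []).append(d)
    merged: list[Detection] = []
    for label, dets in by_class.items():
        boxes = [[d.window.row, d.window.col,
                  d.window.row + d.window.height, d.window.col + d.window.width,
                  d.score] for d in dets]
        changed = True
        while changed:
            changed = False
            out: list[list[float]] = []
            for b in boxes:
                for o in out:
                    if b[0] < o[2] and o[0] < b[2] and b[1] < o[3] and o[1] < b[3]:
                        o[0], o[1] = min(o[0], b[0]), min(o[1], b[1])
                        o[2], o[3] = max(o[2], b[2]), max(o[3], b[3])
                        o[4] = min(o[4], b[4])
                        changed = True
                        break
                else:
                    out.append(list(b))
            boxes = out
        merged.extend(
            Detection(Window(int(b[0]), int(b[1]), int(b[2] - b[0]), int(b[3] - b[1])), label, b[4])
            for b in boxes
        )
    return sorted(merged, key=lambda d: d.window)
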