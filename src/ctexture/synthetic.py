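"""Synthetic texture phantoms for the nine trained attenuation-pattern classes.

No public CT dataset accompanies the attenuation-pattern vocabulary, so every
downstream module is exercised on statistically emulated textures: stationary
correlated noise with controllable mean, variance, skew direction and
roughness, plus concentric banding for the water-halo / fat-halo stratified
patterns. The emulation targets the feature space (moments, co-occurrence
entropy, box-counting dimension), not radiological realism — no beam
hardening, partial-volume or reconstruction-kernel effects.

Every generator is driven by a named seed and is bit-reproducible.
"""

from __future__ import annotations

import importlib.resources
import json
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .features import FdConfig, GlcmSpec, extract_features
from .image import GrayImage
from .patterns import LabeledPatternSet
from .roi import Window

__all__ = [
    "ClassTextureParams",
    "PhantomScene",
    "load_presets",
    "generate_class_texture",
    "generate_phantom",
    "generate_fractal_target",
    "generate_training_set",
    "make_gaussian_pattern_set",
    "make_separated_classes",
]


@dataclass(frozen=True)
class ClassTextureParams:
    """Statistical recipe for one attenuation-pattern texture.

    ``mean_level`` / ``variance`` are the target first and second moments of
    the gray-level histogram. ``skew_direction`` (-1/0/+1) picks the sign of
    the histogram tail. ``correlation_length`` (pixels) smooths the noise
    field, lowering co-occurrence entropy; ``roughness`` in [0, 1] mixes
    unsmoothed noise back in, raising the box-counting dimension of the
    thresholded texture. ``halo_layers`` of 2 or 3 renders concentric bands
    at ``halo_band_levels`` before noise, emulating the stratified halo
    signs.
    """

    label: str
    mean_level: float
    variance: float
    skew_direction: int = 0
    correlation_length: float = 1.0
    roughness: float = 0.5
    halo_layers: int = 0
    halo_band_levels: tuple[float, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.variance < 0:
            raise ValueError("variance must be >= 0")
        if self.skew_direction not in (-1, 0, 1):
            raise ValueError("skew_direction must be -1, 0 or +1")
        if not 0.0 <= self.roughness <= 1.0:
            raise ValueError("roughness must lie in [0, 1]")
        if self.halo_layers not in (0, 2, 3):
            raise ValueError("halo_layers must be 0, 2 or 3")
        if self.halo_layers:
            bands = tuple(self.halo_band_levels)
            if len(bands) != self.halo_layers:
                raise ValueError("halo_band_levels must match halo_layers")
            if len(set(bands)) < 2:
                raise ValueError("halo band levels must not all coincide")
            object.__setattr__(self, "halo_band_levels", bands)


@dataclass(frozen=True)
class PhantomScene:
    """A background texture with embedded, ground-truthed class patches."""

    image: GrayImage
    truth: tuple[tuple[Window, str], ...]
    background: ClassTextureParams
    seed: int


def load_presets():
    """Read the versioned class-preset file shipped with the package.

    Returns ``(params_by_label, window_sizes, background_params, levels)``.
    """
    ref = importlib.resources.files("ctexture").joinpath("data/class_presets.json")
    cfg = json.loads(ref.read_text())
    classes = {
        label: ClassTextureParams(
            label=label,
            mean_level=p["mean_level"],
            variance=p["variance"],
            skew_direction=p["skew_direction"],
            correlation_length=p["correlation_length"],
            roughness=p["roughness"],
            halo_layers=p.get("halo_layers", 0),
            halo_band_levels=tuple(p.get("halo_band_levels", ())),
        )
        for label, p in cfg["classes"].items()
    }
    sizes = {k: tuple(v) for k, v in cfg["window_sizes"].items()}
    bg = cfg["background"]
    background = ClassTextureParams(
        label="background",
        mean_level=bg["mean_level"],
        variance=bg["variance"],
        skew_direction=bg["skew_direction"],
        correlation_length=bg["correlation_length"],
        roughness=bg["roughness"],
    )
    return classes, sizes, background, int(cfg["levels"])


def _noise_field(params: ClassTextureParams, size, rng) -> np.ndarray:
    h, w = size
    if params.skew_direction == 0:
        base = rng.standard_normal((h, w))
    else:
        # shifted exponential has skewness 2; sign flips select the tail side
        base = params.skew_direction * (rng.exponential(1.0, (h, w)) - 1.0)
    if params.correlation_length > 0 and params.roughness < 1.0:
        smooth = ndimage.gaussian_filter(base, params.correlation_length, mode="reflect")
        s = smooth.std()
        if s > 0:
            smooth = smooth / s
        base = params.roughness * base + (1.0 - params.roughness) * smooth
    return base


def _band_base(params: ClassTextureParams, size) -> np.ndarray:
    h, w = size
    rows = np.abs(np.arange(h) - (h - 1) / 2.0) / (h / 2.0)
    cols = np.abs(np.arange(w) - (w - 1) / 2.0) / (w / 2.0)
    radius = np.maximum(rows[:, None], cols[None, :])  # concentric rectangles
    n = params.halo_layers
    band = np.minimum((radius * n).astype(int), n - 1)
    levels = np.asarray(params.halo_band_levels, float)
    # innermost band at the center: band index 0 is the middle layer
    return levels[::-1][band] if n == 3 else levels[band]


def generate_class_texture(
    params: ClassTextureParams, size: tuple[int, int], seed: int, levels: int = 256
) -> GrayImage:
    """Render one texture window with the requested moments.

    The structured field (bands plus correlated noise) is standardized to the
    target mean and variance before integer rounding, so for windows of
    64 x 64 and up the sample mean lands within 2% of ``mean_level`` and the
    sample variance within 10% of ``variance``.
    """
    h, w = size
    if h < 16 or w < 16:
        raise ValueError("texture size must be at least 16 x 16")
    sigma = float(np.sqrt(params.variance))
    if params.mean_level - 4 * sigma < -0.5 or params.mean_level + 4 * sigma > levels + 0.5:
        if sigma > levels / 4:
            raise ValueError(
                f"variance {params.variance} not representable in [0, {levels - 1}]"
            )
    rng = np.random.default_rng(seed)
    fld = _noise_field(params, size, rng)
    if params.halo_layers:
        bands = _band_base(params, size)
        # give the banding most of the contrast budget, noise the rest
        bs = bands.std()
        if bs > 0:
            bands = (bands - bands.mean()) / bs
        fld = (fld - fld.mean()) / max(fld.std(), 1e-12)
        fld = 0.8 * bands + 0.6 * fld
    fld = fld - fld.mean()
    s = fld.std()
    if s > 0 and sigma > 0:
        fld = fld / s * sigma
    else:
        fld = np.zeros_like(fld)
    px = np.clip(np.round(fld + params.mean_level), 0, levels - 1).astype(np.int64)
    return GrayImage(px, levels)


def generate_phantom(
    background: ClassTextureParams,
    patches: list[tuple[str, tuple[int, int]]],
    image_size: tuple[int, int] = (320, 352),
    seed: int = 0,
    class_params: dict[str, ClassTextureParams] | None = None,
    levels: int = 256,
    max_tries: int = 200,
) -> PhantomScene:
    """Background texture with non-overlapping embedded class patches.

    ``patches`` lists (class label, (height, width)) to embed; positions are
    drawn uniformly at random, rejecting overlaps. Ground-truth windows and
    labels are recorded in the returned :class:`PhantomScene`.
    """
    if class_params is None:
        class_params = load_presets()[0]
    rng = np.random.default_rng(seed)
    img = generate_class_texture(
        background, image_size, seed=int(rng.integers(2**31)), levels=levels
    )
    pixels = img.pixels.copy()
    placed: list[tuple[Window, str]] = []
    for label, (ph, pw) in patches:
        if ph > image_size[0] or pw > image_size[1]:
            raise ValueError(f"patch {label} {ph}x{pw} larger than image {image_size}")
        for _ in range(max_tries):
            r = int(rng.integers(0, image_size[0] - ph + 1))
            c = int(rng.integers(0, image_size[1] - pw + 1))
            cand = Window(r, c, ph, pw)
            if all(cand.overlap_fraction(w) == 0.0 for w, _ in placed):
                break
        else:
            raise ValueError(f"could not place patch {label} without overlap")
        tex = generate_class_texture(
            class_params[label], (ph, pw), seed=int(rng.integers(2**31)), levels=levels
        )
        pixels[r : r + ph, c : c + pw] = tex.pixels
        placed.append((cand, label))
    return PhantomScene(
        image=GrayImage(pixels, levels),
        truth=tuple(placed),
        background=background,
        seed=seed,
    )


def generate_fractal_target(kind: str, size: int = 256, depth: int = 6) -> np.ndarray:
    """Deterministic binary rasters with known box-counting dimension.

    ``"square"`` (dimension 2), ``"line"`` (1) and ``"sierpinski"``
    (log 3 / log 2 ~ 1.585; ``size`` must be a power of two >= 2**depth).
    """
    if size < 2:
        raise ValueError("size must be >= 2")
    if kind == "square":
        return np.ones((size, size), dtype=bool)
    if kind == "line":
        mask = np.zeros((size, size), dtype=bool)
        mask[size // 2, :] = True
        return mask
    if kind == "sierpinski":
        if depth < 1 or size & (size - 1) or size < 2**depth:
            raise ValueError("sierpinski needs power-of-two size >= 2**depth")
        mask = np.ones((1, 1), dtype=bool)
        for _ in range(depth):
            z = np.zeros_like(mask)
            top = np.concatenate([mask, z], axis=1)
            bottom = np.concatenate([mask, mask], axis=1)
            mask = np.concatenate([top, bottom], axis=0)
        unit = size // 2**depth
        return np.kron(mask, np.ones((unit, unit), dtype=bool))
    raise ValueError(f"unknown fractal target {kind!r}")


def generate_training_set(
    n_per_class: int,
    seed: int = 0,
    class_params: dict[str, ClassTextureParams] | None = None,
    window_sizes: dict[str, tuple[int, int]] | None = None,
    glcm_spec: GlcmSpec = GlcmSpec(),
    fd_config: FdConfig = FdConfig(),
    levels: int = 256,
    mean_jitter: float = 0.0,
    logvar_jitter: float = 0.0,
) -> LabeledPatternSet:
    """Draw labeled pattern windows and extract their feature vectors.

    Uses the shipped class presets and per-class trained window sizes unless
    overridden. ``mean_jitter`` (gray levels) and ``logvar_jitter`` (log
    units) add per-sample variation of the target mean and variance around
    the class recipe, emulating the within-class spread of real pattern
    windows. Seeds are derived per (class, replicate) so the set is
    reproducible and samples are independent.
    """
    if class_params is None:
        class_params, preset_sizes, _, levels = load_presets()
        if window_sizes is None:
            window_sizes = preset_sizes
    if window_sizes is None:
        window_sizes = {label: (64, 64) for label in class_params}
    ss = np.random.SeedSequence(seed)
    vectors, labels = [], []
    for ci, label in enumerate(class_params):
        child = np.random.SeedSequence(entropy=ss.entropy, spawn_key=(ci,))
        seeds = child.generate_state(n_per_class) % (2**31)
        base = class_params[label]
        for s in seeds:
            p = base
            if mean_jitter > 0 or logvar_jitter > 0:
                jrng = np.random.default_rng(int(s) + 1)
                mean = float(
                    np.clip(
                        base.mean_level + jrng.normal(0.0, mean_jitter),
                        3.0,
                        levels - 4.0,
                    )
                )
                var = float(base.variance * np.exp(jrng.normal(0.0, logvar_jitter)))
                p = ClassTextureParams(
                    label=base.label,
                    mean_level=mean,
                    variance=var,
                    skew_direction=base.skew_direction,
                    correlation_length=base.correlation_length,
                    roughness=base.roughness,
                    halo_layers=base.halo_layers,
                    halo_band_levels=base.halo_band_levels,
                )
            img = generate_class_texture(p, window_sizes[label], int(s), levels)
            vectors.append(extract_features(img, glcm_spec, fd_config))
            labels.append(label)
    return LabeledPatternSet(vectors, labels, list(class_params))


def make_gaussian_pattern_set(
    n_classes: int = 8,
    n_per_class: int = 30,
    separation: float = 6.0,
    seed: int = 0,
) -> LabeledPatternSet:
    """Gaussian feature-space clouds with per-feature class-mean separation.

    Draws six-dimensional feature vectors from unit-variance normal clouds
    whose class means are ``separation`` within-class standard deviations
    apart in *every* feature — the classifier-recovery regime in which a
    k-NN vote should be near-perfect. This synthesizes the feature space
    directly (no textures), isolating the classifier from the extractor.
    """
    rng = np.random.default_rng(seed)
    n_feat = 6
    vectors, labels = [], []
    for i in range(n_classes):
        mean = np.full(n_feat, i * separation, dtype=float)
        pts = rng.standard_normal((n_per_class, n_feat)) + mean
        vectors.extend(pts)
        labels.extend([f"class_{i}"] * n_per_class)
    return LabeledPatternSet(vectors, labels, [f"class_{i}" for i in range(n_classes)])


def make_separated_classes(
    n_classes: int = 8,
    separation: float = 1.0,
    levels: int = 256,
) -> dict[str, ClassTextureParams]:
    """Texture classes whose parameter contrasts scale with one dial.

    ``separation`` in [0, 1] multiplies every between-class parameter
    contrast — gray-level mean, variance, correlation length and roughness —
    away from a common center, so 0 collapses all classes onto one texture
    (chance-level classification) and 1 spreads them across the feasible
    parameter range. Raising the dial makes the downstream classification
    problem easier, which is the monotonicity check for the whole
    texture -> feature -> classifier chain.
    """
    if not 0.0 <= separation <= 1.0:
        raise ValueError("separation must lie in [0, 1]")
    out: dict[str, ClassTextureParams] = {}
    for i in range(n_classes):
        u = 2.0 * i / (n_classes - 1) - 1.0 if n_classes > 1 else 0.0
        c = u * separation
        out[f"class_{i}"] = ClassTextureParams(
            label=f"class_{i}",
            mean_level=128.0 + c * 0.38 * (levels - 1) / 2.0,
            variance=100.0 * 4.0**c,
            correlation_length=max(1.5 + 1.2 * c, 0.0),
            roughness=min(max(0.45 + 0.35 * c, 0.0), 1.0),
        )
    return out
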