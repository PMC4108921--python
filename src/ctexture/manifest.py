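"""Manifests, model files and result serialization.

A pattern manifest is a CSV listing labeled rectangular windows:
``image_path,row,col,height,width,label`` (0-based top-left origin,
size-inclusive). A trained model file is JSON carrying the class vocabulary,
per-class Gaussian models, the z-score normalization and the full feature /
classifier configuration, so a classification run is reproducible from the
file alone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .classify import ClassModel
from .evaluate import ConfusionMatrix
from .features import FdConfig, GlcmSpec, NormalizationModel
from .image import GrayImage, read_image
from .patterns import FeatureVector, LabeledPatternSet
from .roi import Detection, Window

__all__ = [
    "ManifestRecord",
    "PatternManifest",
    "load_manifest",
    "extract_manifest_features",
    "save_model",
    "load_model",
    "save_features_csv",
    "load_features_csv",
    "save_detections_csv",
    "render_overlay",
    "save_confusion_csv",
]

MANIFEST_COLUMNS = ("image_path", "row", "col", "height", "width", "label")
SCHEMA_VERSION = 1


@dataclass(frozen=True)
class ManifestRecord:
    image_path: Path
    window: Window
    label: str


@dataclass(frozen=True)
class PatternManifest:
    records: tuple[ManifestRecord, ...]
    schema_version: int = SCHEMA_VERSION

    def __len__(self) -> int:
        return len(self.records)


def load_manifest(path: str | Path, vocabulary=None) -> PatternManifest:
    """Read and validate a pattern-window manifest CSV.

    Referenced image files must exist; windows must be positive-size; labels
    must belong to ``vocabulary`` when one is given. Violations are reported
    with their (1-based) data row number.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: manifest missing columns {sorted(missing)}")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        img_path = (path.parent / str(row.image_path)).resolve()
        if not img_path.is_file():
            raise ValueError(f"{path}: row {i}: no such image {row.image_path!r}")
        try:
            win = Window(int(row.row), int(row.col), int(row.height), int(row.width))
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: row {i}: {exc}") from exc
        label = str(row.label)
        if vocabulary is not None and label not in vocabulary:
            raise ValueError(f"{path}: row {i}: label {label!r} not in vocabulary")
        records.append(ManifestRecord(img_path, win, label))
    return PatternManifest(tuple(records))


def extract_manifest_features(
    manifest: PatternManifest,
    glcm_spec: GlcmSpec = GlcmSpec(),
    fd_config: FdConfig = FdConfig(),
) -> LabeledPatternSet:
    """Extract the six-feature vector of every manifest window."""
    from .features import extract_features

    cache: dict[Path, GrayImage] = {}
    vectors, labels = [], []
    for rec in manifest.records:
        img = cache.setdefault(rec.image_path, read_image(rec.image_path))
        if not rec.window.inside(img.shape):
            raise ValueError(f"window {rec.window} outside image {rec.image_path}")
        sub = img.crop(rec.window.row, rec.window.col, rec.window.height, rec.window.width)
        vectors.append(extract_features(sub, glcm_spec, fd_config))
        labels.append(rec.label)
    return LabeledPatternSet(vectors, labels)


# ---------------------------------------------------------------------------
# model files


def _glcm_dict(spec: GlcmSpec) -> dict:
    return {"offset": list(spec.offset), "levels": spec.levels}


def _fd_dict(cfg: FdConfig) -> dict:
    return {
        "threshold": cfg.threshold,
        "box_sizes": list(cfg.box_sizes) if cfg.box_sizes else None,
    }


def save_model(
    path: str | Path,
    train: LabeledPatternSet,
    models: list[ClassModel],
    norm: NormalizationModel,
    glcm_spec: GlcmSpec = GlcmSpec(),
    fd_config: FdConfig = FdConfig(),
    knn_k: int = 3,
    distance: str = "euclidean",
    window_sizes: dict | None = None,
    extra: dict | None = None,
) -> None:
    """Write a self-contained JSON model file."""
    doc = {
        "schema_version": SCHEMA_VERSION,
        "class_vocabulary": train.class_vocabulary,
        "training": {
            "vectors": train.to_matrix().tolist(),
            "labels": train.labels,
        },
        "class_models": [
            {
                "label": m.label,
                "mean_vec": m.mean_vec.tolist(),
                "cov": m.cov.tolist(),
                "count": m.count,
            }
            for m in models
        ],
        "normalization": norm.to_dict(),
        "config": {
            "glcm": _glcm_dict(glcm_spec),
            "fd": _fd_dict(fd_config),
            "knn_k": knn_k,
            "distance": distance,
            "window_sizes": {k: list(v) for k, v in (window_sizes or {}).items()},
        },
    }
    if extra:
        doc["provenance"] = extra
    Path(path).write_text(json.dumps(doc, indent=1))


def load_model(path: str | Path) -> dict:
    """Read a model file back into live objects (keys mirror :func:`save_model`)."""
    doc = json.loads(Path(path).read_text())
    train = LabeledPatternSet(
        [FeatureVector.from_array(np.asarray(v)) for v in doc["training"]["vectors"]],
        doc["training"]["labels"],
        doc["class_vocabulary"],
    )
    models = [
        ClassModel(
            label=m["label"],
            mean_vec=np.asarray(m["mean_vec"], float),
            cov=np.asarray(m["cov"], float),
            count=int(m["count"]),
        )
        for m in doc["class_models"]
    ]
    cfg = doc["config"]
    fd_threshold = cfg["fd"]["threshold"]
    return {
        "train": train,
        "models": models,
        "norm": NormalizationModel.from_dict(doc["normalization"]),
        "glcm_spec": GlcmSpec(tuple(cfg["glcm"]["offset"]), cfg["glcm"]["levels"]),
        "fd_config": FdConfig(
            fd_threshold,
            tuple(cfg["fd"]["box_sizes"]) if cfg["fd"]["box_sizes"] else None,
        ),
        "knn_k": int(cfg["knn_k"]),
        "distance": cfg["distance"],
        "window_sizes": {k: tuple(v) for k, v in cfg.get("window_sizes", {}).items()},
        "provenance": doc.get("provenance", {}),
    }


# ---------------------------------------------------------------------------
# feature tables, detections, confusion matrices


def save_features_csv(path: str | Path, data: LabeledPatternSet, sidecar: dict | None = None) -> None:
    """Write `id,label,mean,...,fractal_dim`; optional JSON sidecar of the config."""
    from .patterns import FEATURE_NAMES

    df = pd.DataFrame(data.to_matrix(), columns=list(FEATURE_NAMES))
    df.insert(0, "label", data.labels)
    df.insert(0, "id", range(len(data)))
    df.to_csv(path, index=False)
    if sidecar is not None:
        Path(path).with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_features_csv(path: str | Path) -> LabeledPatternSet:
    from .patterns import FEATURE_NAMES

    df = pd.read_csv(path)
    return LabeledPatternSet(
        df[list(FEATURE_NAMES)].to_numpy(dtype=float),
        df["label"].astype(str).tolist(),
    )


def save_detections_csv(path: str | Path, detections: list[Detection]) -> None:
    rows = [
        {
            "row": d.window.row,
            "col": d.window.col,
            "height": d.window.height,
            "width": d.window.width,
            "class": d.matched_class,
            "score": d.score,
        }
        for d in detections
    ]
    pd.DataFrame(rows, columns=["row", "col", "height", "width", "class", "score"]).to_csv(
        path, index=False
    )


def render_overlay(path: str | Path, img: GrayImage, detections: list[Detection]) -> None:
    """Save a PNG of the image with detection rectangles drawn on top."""
    from PIL import Image, ImageDraw

    scale = 255.0 / max(img.levels - 1, 1)
    base = Image.fromarray((img.pixels * scale).astype(np.uint8), mode="L").convert("RGB")
    draw = ImageDraw.Draw(base)
    for d in detections:
        w = d.window
        draw.rectangle(
            [w.col, w.row, w.col + w.width - 1, w.row + w.height - 1],
            outline=(255, 0, 0),
        )
    base.save(str(path))


def save_confusion_csv(path: str | Path, cm: ConfusionMatrix) -> None:
    df = cm.to_frame()
    df.index.name = "class"
    df.to_csv(path)
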