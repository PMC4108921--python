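"""Grayscale image container and readers.

Images are 2-D arrays of non-negative integer gray levels together with the
number of representable levels (``levels``), which downstream code needs for
gray-level quantization. Readers accept PNG/TIFF (8- or 16-bit) and
single-frame grayscale DICOM; DICOM rescale slope/intercept is applied before
the values are re-quantized to integers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["GrayImage", "read_image"]


@dataclass(frozen=True)
class GrayImage:
    """A 2-D grid of integer intensities in ``[0, levels - 1]``.

    Parameters
    ----------
    pixels
        2-D integer array, row-major, origin at top-left.
    levels
        Number of representable gray levels (256 for 8-bit input).
    pixel_spacing
        Optional (row, col) physical spacing in mm, carried from DICOM.
    """

    pixels: np.ndarray
    levels: int
    pixel_spacing: tuple[float, float] | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("GrayImage requires a non-empty 2-D pixel array")
        if not np.issubdtype(px.dtype, np.integer):
            raise ValueError(f"GrayImage pixels must be integers, got {px.dtype}")
        if self.levels < 2:
            raise ValueError("levels must be >= 2")
        if px.min() < 0 or px.max() >= self.levels:
            raise ValueError(
                f"intensities must lie in [0, {self.levels - 1}], "
                f"got range [{px.min()}, {px.max()}]"
            )
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def crop(self, row: int, col: int, height: int, width: int) -> "GrayImage":
        """Return the ``height x width`` sub-image with top-left at (row, col)."""
        if row < 0 or col < 0 or row + height > self.height or col + width > self.width:
            raise ValueError(
                f"window ({row},{col},{height},{width}) exceeds image bounds "
                f"{self.shape}"
            )
        return GrayImage(
            self.pixels[row : row + height, col : col + width],
            self.levels,
            self.pixel_spacing,
        )

    @classmethod
    def from_array(cls, arr: np.ndarray, levels: int | None = None) -> "GrayImage":
        """Build from any integer array, inferring ``levels`` from dtype if omitted."""
        arr = np.asarray(arr)
        if levels is None:
            if arr.dtype == np.uint16 or (arr.size and arr.max() > 255):
                levels = 65536
            else:
                levels = 256
        return cls(arr.astype(np.int64), levels)


def _luminance(arr: np.ndarray) -> np.ndarray:
    # ITU-R 601 weights; applied when a color image is passed where gray is expected
    return (0.299 * arr[..., 0] + 0.587 * arr[..., 1] + 0.114 * arr[..., 2]).round()


def _read_dicom(path: Path) -> GrayImage:
    import pydicom

    ds = pydicom.dcmread(str(path))
    arr = ds.pixel_array.astype(np.float64)
    if arr.ndim != 2:
        raise ValueError(f"{path}: only single-frame grayscale DICOM is supported")
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    arr = slope * arr + intercept
    # shift rescaled values (possibly negative, e.g. Hounsfield-like) to a
    # non-negative integer grid; quantization downstream works on the range
    arr = np.round(arr - arr.min()).astype(np.int64)
    levels = int(arr.max()) + 1 if arr.max() >= 256 else 256
    spacing = None
    if getattr(ds, "PixelSpacing", None) is not None:
        spacing = (float(ds.PixelSpacing[0]), float(ds.PixelSpacing[1]))
    return GrayImage(arr, max(levels, 2), spacing)


def _read_raster(path: Path) -> GrayImage:
    suffix = path.suffix.lower()
    if suffix in {".tif", ".tiff"}:
        import tifffile

        arr = tifffile.imread(str(path))
    else:
        from PIL import Image

        with Image.open(str(path)) as im:
            arr = np.asarray(im)
    if arr.ndim == 3:
        import warnings

        warnings.warn(f"{path}: multi-channel image converted to luminance")
        arr = _luminance(arr.astype(np.float64))
    levels = 65536 if np.asarray(arr).dtype == np.uint16 else 256
    return GrayImage(np.asarray(arr).astype(np.int64), levels)


def read_image(path: str | Path, format_hint: str | None = None) -> GrayImage:
    """Read a grayscale image from PNG, TIFF or DICOM.

    ``format_hint`` may be ``"dicom"``, ``"png"`` or ``"tiff"``; by default the
    file suffix decides. Raises ``IOError``/``ValueError`` on unreadable input;
    no partial result is returned.
    """
    path = Path(path)
    if not path.is_file():
        raise IOError(f"no such image file: {path}")
    hint = (format_hint or path.suffix.lstrip(".")).lower()
    if hint in {"dcm", "dicom"}:
        return _read_dicom(path)
    return _read_raster(path)
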