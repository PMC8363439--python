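"""Reading and writing CT slices and masks.

The segmentation operates on 8-bit grayscale bitmaps.  Clinical input
arrives as single-frame DICOM; :func:`load_dicom_slice` recovers calibrated
Hounsfield units (HU) and :func:`window_to_bitmap` maps a chosen HU window
linearly onto the 0-255 gray range.  The default window (center 300 HU,
width 1500 HU) is a standard bone window suitable for knee osteo-anatomy.

Conventions used throughout the package: images are 2-D, row-major,
0-based ``(row, col)``; masks are binary with 1 = foreground (bone).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = [
    "IntensityImage",
    "WindowSpec",
    "load_dicom_slice",
    "window_to_bitmap",
    "load_bitmap",
    "save_bitmap",
    "load_mask",
    "save_mask",
]

#: Default CT display window for bone (Hounsfield units).
DEFAULT_BONE_WINDOW_CENTER = 300.0
DEFAULT_BONE_WINDOW_WIDTH = 1500.0


@dataclass(frozen=True)
class WindowSpec:
    """A CT display window: ``[center - width/2, center + width/2]`` in HU."""

    center: float = DEFAULT_BONE_WINDOW_CENTER
    width: float = DEFAULT_BONE_WINDOW_WIDTH

    def __post_init__(self) -> None:
        if not self.width > 0:
            raise ValueError(f"window width must be > 0, got {self.width}")


@dataclass
class IntensityImage:
    """A 2-D 8-bit grayscale image, the substrate of segmentation.

    Parameters
    ----------
    values
        ``(height, width)`` array of gray values; stored as ``uint8``.
    provenance
        Free text recording where the pixels came from (a file path,
        ``"phantom"``, ...).
    """

    values: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.values)
        if arr.ndim != 2 or arr.shape[0] < 1 or arr.shape[1] < 1:
            raise ValueError(f"expected a non-empty 2-D image, got shape {arr.shape}")
        if arr.dtype != np.uint8:
            if np.any((arr < 0) | (arr > 255)):
                raise ValueError("gray values must lie in [0, 255]")
            arr = arr.astype(np.uint8)
        self.values = arr

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def load_dicom_slice(path: str | Path) -> np.ndarray:
    """Read a single-frame grayscale DICOM slice as Hounsfield units.

    The stored pixel values are mapped through the modality rescale
    ``HU = slope * stored + intercept`` (slope defaults to 1, intercept
    to 0 when absent).

    Returns
    -------
    numpy.ndarray
        ``(rows, cols)`` float64 array of HU values.

    Raises
    ------
    FileNotFoundError
        If *path* does not exist.
    ValueError
        For multi-frame or non-grayscale DICOM objects.
    """
    import pydicom

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    ds = pydicom.dcmread(path)
    n_frames = int(getattr(ds, "NumberOfFrames", 1) or 1)
    if n_frames != 1:
        raise ValueError(f"unsupported input: multi-frame DICOM ({n_frames} frames)")
    samples = int(getattr(ds, "SamplesPerPixel", 1) or 1)
    if samples != 1:
        raise ValueError("unsupported input: color DICOM (SamplesPerPixel != 1)")
    stored = ds.pixel_array.astype(np.float64)
    if stored.ndim != 2:
        raise ValueError(f"unsupported input: expected a 2-D frame, got shape {stored.shape}")
    slope = float(getattr(ds, "RescaleSlope", 1.0) or 1.0)
    intercept = float(getattr(ds, "RescaleIntercept", 0.0) or 0.0)
    return slope * stored + intercept


def _round_half_up(x: np.ndarray) -> np.ndarray:
    # np.rint rounds half to even; the I/O contract is half-up so tests
    # can pin exact gray values.
    return np.floor(x + 0.5)


def window_to_bitmap(hu: np.ndarray, window: WindowSpec | None = None) -> IntensityImage:
    """Map a HU slice onto 8-bit gray via a linear display window.

    HU at the lower window edge maps to 0, the upper edge to 255; values
    outside the window clamp.  Rounding is half-up, so the mapping is
    deterministic and monotone non-decreasing.
    """
    if window is None:
        window = WindowSpec()
    hu = np.asarray(hu, dtype=np.float64)
    lo = window.center - window.width / 2.0
    scaled = (hu - lo) / window.width * 255.0
    gray = np.clip(_round_half_up(scaled), 0, 255).astype(np.uint8)
    return IntensityImage(gray, provenance="windowed")


def load_bitmap(path: str | Path) -> IntensityImage:
    """Load an 8-bit grayscale PNG or BMP.

    Color and 16-bit inputs are rejected rather than silently converted:
    CT slices are grayscale and an unexpected mode almost always signals a
    pipeline error upstream.
    """
    path = Path(path)
    try:
        img = Image.open(path)
        img.load()
    except FileNotFoundError:
        raise
    except Exception as exc:  # PIL raises various subclasses for bad files
        raise ValueError(f"unreadable image file {path}: {exc}") from exc
    if img.mode != "L":
        raise ValueError(
            f"unsupported bit depth / mode {img.mode!r} in {path}: "
            "expected 8-bit grayscale ('L')"
        )
    return IntensityImage(np.asarray(img, dtype=np.uint8), provenance=str(path))


def save_bitmap(image: IntensityImage, path: str | Path) -> None:
    """Write an 8-bit grayscale image as PNG or BMP (by extension)."""
    Image.fromarray(image.values, mode="L").save(Path(path))


def load_mask(path: str | Path):
    """Load a binary mask image; 255 maps to foreground (1), 0 to background.

    Raises
    ------
    ValueError
        If any pixel is neither 0 nor 255.
    """
    from .graph_model import LabelImage

    img = load_bitmap(path)
    vals = img.values
    bad = ~np.isin(vals, (0, 255))
    if bad.any():
        offenders = np.unique(vals[bad])
        raise ValueError(
            f"mask {path} contains values other than {{0, 255}}: {offenders.tolist()}"
        )
    return LabelImage((vals == 255).astype(np.uint8))


def save_mask(mask, path: str | Path) -> None:
    """Write a binary labeling as a {0, 255} grayscale image."""
    arr = (np.asarray(mask.labels, dtype=np.uint8) * 255).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(Path(path))
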