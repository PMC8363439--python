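"""Automatic marker (trimap) generation and manual corrections.

Two automatic front-ends replace manual seed placement:

* threshold trimap — a global Otsu threshold splits the gray histogram;
  pixels well above it become object marks, well below background marks,
  and a band of ``margin`` gray levels around it is left for the cut to
  decide;
* morphological marks — the thresholded mask is opened with a horizontal
  1x3 structuring element, which deletes isolated bright noise and
  structures thinner than three pixels, and the opened mask becomes the
  object marks; background marks are the complement of the (un-opened)
  mask's 3x3 dilation, keeping a safety band around the object.

Manual correction strokes override automatic marks, later strokes winning.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage

from .imageio import IntensityImage

__all__ = [
    "MarkerClass",
    "MarkerImage",
    "StructuringElement",
    "CorrectionStroke",
    "HORIZONTAL_1X3",
    "SQUARE_3X3",
    "otsu_threshold",
    "trimap_from_threshold",
    "erode",
    "dilate",
    "morphological_open",
    "morphological_close",
    "morphology_markers",
    "apply_corrections",
    "markers_from_seeds",
    "markers_from_labeling",
    "load_trimap",
    "save_trimap",
    "load_strokes",
]


class MarkerClass(IntEnum):
    """Per-pixel marker classes of a trimap."""

    BACKGROUND = 0
    OBJECT = 1
    UNKNOWN = 2


#: PNG encoding of marker classes (and its inverse).
_CLASS_TO_GRAY = {MarkerClass.BACKGROUND: 0, MarkerClass.OBJECT: 255, MarkerClass.UNKNOWN: 128}
_GRAY_TO_CLASS = {v: k for k, v in _CLASS_TO_GRAY.items()}


@dataclass
class MarkerImage:
    """Per-pixel three-class trimap: object / background / to-be-segmented."""

    classes: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.classes)
        if arr.ndim != 2:
            raise ValueError(f"classes must be 2-D, got shape {arr.shape}")
        if not np.isin(arr, (0, 1, 2)).all():
            raise ValueError("classes must be MarkerClass values 0, 1 or 2")
        self.classes = arr.astype(np.uint8)

    @property
    def height(self) -> int:
        return self.classes.shape[0]

    @property
    def width(self) -> int:
        return self.classes.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.classes.shape

    def count(self, cls: MarkerClass) -> int:
        return int((self.classes == cls).sum())


@dataclass(frozen=True)
class StructuringElement:
    """Binary stencil of a morphological operation, with its anchor."""

    shape: tuple[tuple[int, ...], ...]
    anchor: tuple[int, int]

    def __post_init__(self) -> None:
        arr = self.stencil
        if arr.size == 0 or not arr.any():
            raise ValueError("structuring element stencil must be non-empty")
        r, c = self.anchor
        if not (0 <= r < arr.shape[0] and 0 <= c < arr.shape[1]):
            raise ValueError(f"anchor {self.anchor} outside stencil of shape {arr.shape}")

    @property
    def stencil(self) -> np.ndarray:
        return np.asarray(self.shape, dtype=bool)

    @property
    def origin(self) -> tuple[int, int]:
        """scipy.ndimage origin offset equivalent to this anchor."""
        arr = self.stencil
        return (self.anchor[0] - arr.shape[0] // 2, self.anchor[1] - arr.shape[1] // 2)


#: Horizontal 1x3 structuring element — the opening stencil of the
#: morphological marker pipeline.
HORIZONTAL_1X3 = StructuringElement(shape=((1, 1, 1),), anchor=(0, 1))
#: 3x3 square used to dilate the threshold mask before taking background marks.
SQUARE_3X3 = StructuringElement(shape=((1, 1, 1), (1, 1, 1), (1, 1, 1)), anchor=(1, 1))


@dataclass(frozen=True)
class CorrectionStroke:
    """A manual correction: pixels reassigned to one marker class."""

    pixels: tuple
    assigned_class: MarkerClass

    def __init__(self, pixels: Iterable, assigned_class: MarkerClass):
        object.__setattr__(
            self, "pixels", tuple((int(r), int(c)) for r, c in pixels)
        )
        cls = MarkerClass(assigned_class)
        if cls not in (MarkerClass.OBJECT, MarkerClass.BACKGROUND):
            raise ValueError("strokes assign OBJECT or BACKGROUND")
        object.__setattr__(self, "assigned_class", cls)


# ---------------------------------------------------------------------------
# thresholding

def otsu_threshold(image: IntensityImage) -> int:
    """Global threshold maximizing between-class variance of the histogram.

    Candidate levels t split pixels into {gray < t} and {gray >= t}; the
    level with the largest between-class variance wins, the lowest such
    level on ties.

    Raises
    ------
    ValueError
        For a constant image (no split exists).
    """
    hist = np.bincount(image.values.ravel(), minlength=256).astype(np.float64)
    if np.count_nonzero(hist) < 2:
        raise ValueError("cannot threshold a constant image")
    total = hist.sum()
    levels = np.arange(256, dtype=np.float64)
    # cumulative weight and mean of the {gray < t} class for t = 0..255
    w0 = np.concatenate(([0.0], np.cumsum(hist)))[:-1] / total  # weight below t
    m0sum = np.concatenate(([0.0], np.cumsum(hist * levels)))[:-1] / total
    w1 = 1.0 - w0
    mu = (hist * levels).sum() / total  # overall mean
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = m0sum / w0
        mu1 = (mu - m0sum) / w1
        var_between = w0 * w1 * (mu0 - mu1) ** 2
    var_between[~np.isfinite(var_between)] = -np.inf  # empty class: invalid split
    best = int(np.argmax(var_between))  # argmax takes the lowest tie
    return best


def trimap_from_threshold(image: IntensityImage, threshold: float, margin: float = 10) -> MarkerImage:
    """Three-class marking around a global threshold.

    gray >= threshold + margin -> OBJECT; gray <= threshold - margin ->
    BACKGROUND; the band in between is UNKNOWN, left to the cut.

    Raises
    ------
    ValueError
        If margin < 0, or the margin empties a class (the error names it).
    """
    if margin < 0:
        raise ValueError("margin must be >= 0")
    g = image.values.astype(np.float64)
    classes = np.full(image.shape, MarkerClass.UNKNOWN, dtype=np.uint8)
    classes[g >= threshold + margin] = MarkerClass.OBJECT
    classes[(g <= threshold - margin) & (g < threshold + margin)] = MarkerClass.BACKGROUND
    markers = MarkerImage(classes)
    for cls in (MarkerClass.OBJECT, MarkerClass.BACKGROUND):
        if markers.count(cls) == 0:
            raise ValueError(
                f"margin {margin} leaves no {cls.name} pixels at threshold {threshold}"
            )
    return markers


# ---------------------------------------------------------------------------
# binary morphology

def _as_binary(mask: np.ndarray) -> np.ndarray:
    arr = np.asarray(mask)
    if arr.ndim != 2:
        raise ValueError("mask must be 2-D")
    if not np.isin(arr, (0, 1)).all() and arr.dtype != bool:
        raise ValueError("mask must be binary")
    return arr.astype(bool)


def erode(mask: np.ndarray, se: StructuringElement) -> np.ndarray:
    """Binary erosion; pixels beyond the border count as background."""
    return ndimage.binary_erosion(
        _as_binary(mask), structure=se.stencil, origin=se.origin, border_value=0
    )


def dilate(mask: np.ndarray, se: StructuringElement) -> np.ndarray:
    """Binary dilation; pixels beyond the border count as background."""
    # dilation reflects the SE about the anchor, so negate the origin to
    # keep erode/dilate adjoint (opening anti-extensive) for asymmetric SEs
    origin = (-se.origin[0], -se.origin[1])
    return ndimage.binary_dilation(
        _as_binary(mask), structure=se.stencil, origin=origin, border_value=0
    )


def morphological_open(mask: np.ndarray, se: StructuringElement = HORIZONTAL_1X3) -> np.ndarray:
    """Opening: erosion then dilation.  Removes structures smaller than the
    stencil (isolated pixels, runs shorter than 3 for the default 1x3 SE)
    without growing what remains; idempotent and anti-extensive."""
    return dilate(erode(mask, se), se)


def morphological_close(mask: np.ndarray, se: StructuringElement = HORIZONTAL_1X3) -> np.ndarray:
    """Closing: dilation then erosion.  Fills gaps smaller than the stencil.

    Exposed for completeness; the default marker pipeline uses opening only.
    """
    return erode(dilate(mask, se), se)


# ---------------------------------------------------------------------------
# automatic marker pipelines

def morphology_markers(image: IntensityImage) -> MarkerImage:
    """Automatic marks by morphological opening of the threshold mask.

    Pipeline: Otsu threshold -> binary mask (gray >= threshold) -> opening
    with the horizontal 1x3 SE -> opened mask = OBJECT marks.  BACKGROUND
    marks are the complement of the opened mask dilated by a 3x3 square,
    leaving a one-pixel uncertainty rim as UNKNOWN.  Taking the background
    relative to the *opened* mask (not the raw threshold mask) is what
    makes this front-end noise-robust: isolated bright noise removed by
    the opening lands in the background marks, so the background model
    sees the noise tail instead of leaving those pixels undecided.

    Raises
    ------
    ValueError
        If opening empties the object marks (image too noisy or structures
        thinner than the stencil) — use a larger phantom or manual seeds —
        or if the dilation covers the whole image (no background left).
    """
    t = otsu_threshold(image)
    mask = image.values >= t
    opened = morphological_open(mask, HORIZONTAL_1X3)
    if not opened.any():
        raise ValueError(
            "morphological opening removed every object mark (structures thinner "
            "than the 1x3 stencil); use a larger image/phantom or manual seeds"
        )
    background = ~dilate(opened, SQUARE_3X3)
    if not background.any():
        raise ValueError("no background marks: threshold foreground fills the image")
    classes = np.full(image.shape, MarkerClass.UNKNOWN, dtype=np.uint8)
    classes[opened] = MarkerClass.OBJECT
    classes[background] = MarkerClass.BACKGROUND
    return MarkerImage(classes)


def apply_corrections(markers: MarkerImage, strokes: Sequence[CorrectionStroke]) -> MarkerImage:
    """Apply manual correction strokes; later strokes override earlier ones
    and all override the automatic marks.  Returns a new MarkerImage."""
    classes = markers.classes.copy()
    h, w = markers.shape
    for stroke in strokes:
        for r, c in stroke.pixels:
            if not (0 <= r < h and 0 <= c < w):
                raise ValueError(f"stroke pixel ({r}, {c}) out of bounds for {h}x{w}")
            classes[r, c] = stroke.assigned_class
    return MarkerImage(classes)


# ---------------------------------------------------------------------------
# conversions and file formats

def markers_from_seeds(seeds, shape: tuple[int, int]) -> MarkerImage:
    """Expand a SeedSet into a trimap (everything unmarked is UNKNOWN)."""
    seeds.check_bounds(shape)
    classes = np.full(shape, MarkerClass.UNKNOWN, dtype=np.uint8)
    for r, c in seeds.object_seeds:
        classes[r, c] = MarkerClass.OBJECT
    for r, c in seeds.background_seeds:
        classes[r, c] = MarkerClass.BACKGROUND
    return MarkerImage(classes)


def markers_from_labeling(labeling) -> MarkerImage:
    """Treat a full labeling as marks (1 -> OBJECT, 0 -> BACKGROUND)."""
    classes = np.where(
        labeling.labels.astype(bool), MarkerClass.OBJECT, MarkerClass.BACKGROUND
    ).astype(np.uint8)
    return MarkerImage(classes)


def save_trimap(markers: MarkerImage, path) -> None:
    """Write a trimap PNG: 0 = background, 255 = object, 128 = unknown."""
    from PIL import Image

    gray = np.zeros(markers.shape, dtype=np.uint8)
    for cls, val in _CLASS_TO_GRAY.items():
        gray[markers.classes == cls] = val
    Image.fromarray(gray, mode="L").save(Path(path))


def load_trimap(path) -> MarkerImage:
    """Read a trimap PNG written by :func:`save_trimap`."""
    from .imageio import load_bitmap

    img = load_bitmap(path)
    vals = img.values
    bad = ~np.isin(vals, list(_GRAY_TO_CLASS))
    if bad.any():
        raise ValueError(
            f"trimap {path} contains gray values other than 0/128/255: "
            f"{np.unique(vals[bad]).tolist()}"
        )
    classes = np.full(vals.shape, MarkerClass.UNKNOWN, dtype=np.uint8)
    for val, cls in _GRAY_TO_CLASS.items():
        classes[vals == val] = cls
    return MarkerImage(classes)


def load_strokes(path) -> list[CorrectionStroke]:
    """Read correction strokes from text lines ``row col class`` where class
    is ``object`` or ``background`` (one stroke per line)."""
    strokes = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 3:
            raise ValueError(f"{path}:{lineno}: expected 'row col class'")
        r, c, name = int(parts[0]), int(parts[1]), parts[2].lower()
        if name not in ("object", "background"):
            raise ValueError(f"{path}:{lineno}: class must be object or background")
        cls = MarkerClass.OBJECT if name == "object" else MarkerClass.BACKGROUND
        strokes.append(CorrectionStroke(pixels=[(r, c)], assigned_class=cls))
    return strokes
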