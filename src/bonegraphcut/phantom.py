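"""Synthetic knee-CT phantom slices with exact ground truth.

No patient data ships with the package; every quantitative claim is made
on phantoms that emulate the gray structure the segmentation exploits in a
real axial knee slice: two condyle-like ellipses of bone (bright cortical
rim around a darker trabecular interior) on a soft-tissue background,
degraded by Gaussian blur (a partial-volume surrogate) and additive
Gaussian noise.  The ground-truth mask is the union of the full ellipses,
rasterized *before* any corruption, so blur and noise never move the gold
standard.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .graph_model import LabelImage
from .imageio import IntensityImage

__all__ = ["PhantomSpec", "generate_phantom", "generate_suite"]


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic knee-CT slice.

    Defaults draw two femoral-condyle-like ellipses on a 128x128 field,
    with gray means 60 (soft tissue), 140 (trabecular bone) and 220
    (cortical bone) — clearly tri-modal, as bone-windowed knee CT is.
    ``blur_sigma`` (pixels) emulates partial-volume edge blur and
    ``noise_sd`` (gray levels) acquisition noise; the defaults are a
    sub-pixel blur (sharp bone-kernel CT) and no noise.
    """

    height: int = 128
    width: int = 128
    condyle_centers: tuple[tuple[float, float], tuple[float, float]] = ((62.0, 40.0), (66.0, 88.0))
    condyle_axes: tuple[tuple[float, float], tuple[float, float]] = ((24.0, 18.0), (22.0, 16.0))
    cortical_thickness: float = 3.0
    intensity_background: float = 60.0
    intensity_trabecular: float = 140.0
    intensity_cortical: float = 220.0
    blur_sigma: float = 0.5
    noise_sd: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.height < 1 or self.width < 1:
            raise ValueError("phantom must be at least 1x1")
        if not (
            0 <= self.intensity_background < self.intensity_trabecular < self.intensity_cortical <= 255
        ):
            raise ValueError(
                "intensities must satisfy 0 <= background < trabecular < cortical <= 255"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.blur_sigma < 0:
            raise ValueError("blur_sigma must be >= 0")
        if self.cortical_thickness < 0:
            raise ValueError("cortical_thickness must be >= 0")
        if len(self.condyle_centers) != len(self.condyle_axes):
            raise ValueError("one axes pair per center required")
        for (cr, cc), (ar, ac) in zip(self.condyle_centers, self.condyle_axes):
            if ar <= 0 or ac <= 0:
                raise ValueError("ellipse semi-axes must be > 0")
            if not (cr - ar >= 0 and cr + ar <= self.height - 1 and cc - ac >= 0 and cc + ac <= self.width - 1):
                raise ValueError(
                    f"ellipse center ({cr}, {cc}) axes ({ar}, {ac}) out of bounds "
                    f"for {self.height}x{self.width}"
                )


def _inside_ellipse(rows, cols, center, axes) -> np.ndarray:
    cr, cc = center
    ar, ac = axes
    return ((rows - cr) / ar) ** 2 + ((cols - cc) / ac) ** 2 <= 1.0


def generate_phantom(spec: PhantomSpec) -> tuple[IntensityImage, LabelImage]:
    """Rasterize one phantom and its exact ground-truth bone mask.

    Interiors are painted at the trabecular intensity and a rim of
    ``cortical_thickness`` pixels at the cortical intensity; the truth mask
    (bone = cortical + trabecular, matching the bone-tissue segmentation
    goal) is fixed before Gaussian blur and seeded additive noise are
    applied and the result is clamped to [0, 255].  Deterministic given
    ``rng_seed``.
    """
    rows, cols = np.mgrid[0 : spec.height, 0 : spec.width].astype(np.float64)
    img = np.full((spec.height, spec.width), spec.intensity_background, dtype=np.float64)
    truth = np.zeros((spec.height, spec.width), dtype=bool)
    for center, axes in zip(spec.condyle_centers, spec.condyle_axes):
        outer = _inside_ellipse(rows, cols, center, axes)
        inner_axes = (
            max(axes[0] - spec.cortical_thickness, 0.0),
            max(axes[1] - spec.cortical_thickness, 0.0),
        )
        if inner_axes[0] > 0 and inner_axes[1] > 0:
            inner = _inside_ellipse(rows, cols, center, inner_axes)
        else:
            inner = np.zeros_like(outer)
        img[outer] = spec.intensity_cortical
        img[inner] = spec.intensity_trabecular
        truth |= outer
    if spec.blur_sigma > 0:
        img = ndimage.gaussian_filter(img, sigma=spec.blur_sigma)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.rng_seed)
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    gray = np.clip(np.floor(img + 0.5), 0, 255).astype(np.uint8)
    return (
        IntensityImage(gray, provenance=f"phantom(seed={spec.rng_seed})"),
        LabelImage(truth.astype(np.uint8)),
    )


def generate_suite(
    base: PhantomSpec,
    noise_sds: list[float],
    n_per_level: int = 1,
    seed0: int = 0,
) -> list[tuple[PhantomSpec, IntensityImage, LabelImage]]:
    """A deterministic benchmark suite: ``n_per_level`` phantoms per noise
    level with consecutive seeds ``seed0, seed0 + 1, ...``.

    Geometry is jittered per phantom (centers by up to +-3 pixels, semi-axes
    by up to +-2) from a stream derived from the phantom seed, so every
    slice differs while all ellipses stay in-bounds for the default base.
    """
    if n_per_level < 1:
        raise ValueError("n_per_level must be >= 1")
    out = []
    seed = seed0
    for sd in noise_sds:
        for _ in range(n_per_level):
            jrng = np.random.default_rng([seed, 9151])
            centers = tuple(
                (cr + float(jrng.integers(-3, 4)), cc + float(jrng.integers(-3, 4)))
                for cr, cc in base.condyle_centers
            )
            axes = tuple(
                (ar + float(jrng.integers(-2, 3)), ac + float(jrng.integers(-2, 3)))
                for ar, ac in base.condyle_axes
            )
            spec = replace(
                base,
                condyle_centers=centers,
                condyle_axes=axes,
                noise_sd=float(sd),
                rng_seed=seed,
            )
            image, truth = generate_phantom(spec)
            out.append((spec, image, truth))
            seed += 1
    return out
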