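"""End-to-end segmentation variants.

Three front-ends feed the same energy model and solver:

* ``manual`` — user-supplied object/background seed pixels (the classic
  interactively-seeded graph cut);
* ``threshold`` — automatic Otsu trimap: pixels far from the global
  threshold become hard marks, a margin band is decided by the cut;
* ``morphology`` — marks from morphological opening of the threshold mask
  (robust to isolated noise), optionally corrected by strokes, followed by
  an iterate-until-stable refinement: likelihoods are re-estimated from the
  current labeling (marks stay hard), the graph rebuilt and re-solved until
  the labeling reaches a fixed point or ``max_iter``.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .graph_model import (
    GraphCutParams,
    IntensityModel,
    LabelImage,
    SeedSet,
    build_graph,
    estimate_intensity_model,
)
from .imageio import IntensityImage
from .markers import (
    CorrectionStroke,
    MarkerImage,
    apply_corrections,
    markers_from_labeling,
    markers_from_seeds,
    morphology_markers,
    otsu_threshold,
    trimap_from_threshold,
)
from .maxflow import solve_min_cut

__all__ = [
    "SegmentationRun",
    "segment_manual",
    "segment_threshold_gc",
    "segment_morphology_gc",
    "sparse_seeds_from_truth",
]

VARIANTS = ("manual", "threshold", "morphology")


@dataclass
class SegmentationRun:
    """Record of one segmentation: result, energy trace and bookkeeping.

    ``energy_trace[i]`` is the cut value (= labeling energy under that
    iteration's intensity model) of iteration ``i``; single-pass variants
    have a one-element trace.  ``converged`` is False only when the
    morphology refinement hit ``max_iter`` without reaching a labeling
    fixed point — reported here rather than raised.
    """

    variant: str
    params: GraphCutParams
    iterations_used: int
    final_labeling: LabelImage
    energy_trace: list[float]
    markers: MarkerImage
    final_model: IntensityModel | None = None
    converged: bool = True
    changed_pixels: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        if self.iterations_used < 1:
            raise ValueError("iterations_used must be >= 1")


def _single_pass(image, markers, params, variant) -> SegmentationRun:
    model = estimate_intensity_model(image, markers, params.bins, params.smoothing_eps)
    graph = build_graph(image, markers, params, model=model)
    cut = solve_min_cut(graph)
    return SegmentationRun(
        variant=variant,
        params=params,
        iterations_used=1,
        final_labeling=cut.labeling,
        energy_trace=[cut.flow_value],
        markers=markers,
        final_model=model,
        changed_pixels=[int(np.prod(image.shape))],
    )


def segment_manual(
    image: IntensityImage, seeds: SeedSet, params: GraphCutParams | None = None
) -> SegmentationRun:
    """Classic seeded graph cut: one build + one min-cut solve."""
    if params is None:
        params = GraphCutParams()
    markers = markers_from_seeds(seeds, image.shape)
    return _single_pass(image, markers, params, "manual")


def segment_threshold_gc(
    image: IntensityImage,
    params: GraphCutParams | None = None,
    margin: float = 10,
) -> SegmentationRun:
    """Automatic threshold-trimap graph cut (single pass).

    With ``margin = 0`` every pixel is hard-marked and the result equals
    pure Otsu thresholding; larger margins hand the uncertain gray band to
    the cut.
    """
    if params is None:
        params = GraphCutParams()
    t = otsu_threshold(image)
    markers = trimap_from_threshold(image, t, margin)
    return _single_pass(image, markers, params, "threshold")


def segment_morphology_gc(
    image: IntensityImage,
    params: GraphCutParams | None = None,
    strokes: Sequence[CorrectionStroke] | None = None,
    max_iter: int = 10,
    reestimate: bool = True,
) -> SegmentationRun:
    """Morphological-marker graph cut with iterated refinement.

    After the initial solve, the intensity models are re-estimated from
    the current labeling (the opening-derived marks and any correction
    strokes stay hard) and the cut re-solved, until the labeling stops
    changing or ``max_iter`` passes are used.  ``reestimate=False``
    disables the refinement loop (single pass).  Each re-solve is optimal
    for its model, so the energy trace is non-increasing.
    """
    if params is None:
        params = GraphCutParams()
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    markers = morphology_markers(image)
    if strokes:
        markers = apply_corrections(markers, strokes)

    model = estimate_intensity_model(image, markers, params.bins, params.smoothing_eps)
    graph = build_graph(image, markers, params, model=model)
    cut = solve_min_cut(graph)
    labeling = cut.labeling
    trace = [cut.flow_value]
    changed = [int(np.prod(image.shape))]
    converged = True

    if reestimate:
        converged = False
        for _ in range(1, max_iter):
            model = estimate_intensity_model(
                image, markers_from_labeling(labeling), params.bins, params.smoothing_eps
            )
            graph = build_graph(image, markers, params, model=model)
            cut = solve_min_cut(graph)
            n_changed = int((cut.labeling.labels != labeling.labels).sum())
            trace.append(cut.flow_value)
            changed.append(n_changed)
            labeling = cut.labeling
            if n_changed == 0:
                converged = True
                break
        else:
            # loop exhausted without a fixed point
            converged = False
        if max_iter == 1:
            converged = True

    return SegmentationRun(
        variant="morphology",
        params=params,
        iterations_used=len(trace),
        final_labeling=labeling,
        energy_trace=trace,
        markers=markers,
        final_model=model,
        converged=converged,
        changed_pixels=changed,
    )


def sparse_seeds_from_truth(
    truth: LabelImage, n_object: int = 5, n_background: int = 5, seed: int = 0
) -> SeedSet:
    """Benchmark protocol for the manual variant: sample a few seed pixels
    from the ground truth with a fixed RNG seed (deterministic)."""
    fg = np.argwhere(truth.labels == 1)
    bg = np.argwhere(truth.labels == 0)
    if len(fg) < n_object or len(bg) < n_background:
        raise ValueError("truth has too few pixels of a class to sample seeds")
    rng = np.random.default_rng([seed, 40937])
    fg_idx = rng.choice(len(fg), size=n_object, replace=False)
    bg_idx = rng.choice(len(bg), size=n_background, replace=False)
    return SeedSet(
        object_seeds=[tuple(map(int, fg[i])) for i in fg_idx],
        background_seeds=[tuple(map(int, bg[i])) for i in bg_idx],
    )
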