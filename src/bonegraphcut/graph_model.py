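"""The segmentation energy model and its s-t graph encoding.

A binary labeling ``L`` (1 = foreground/bone, 0 = background) is scored by

    E(L) = lambda * sum_p R_p(l_p)  +  sum_{(p,q) in N} A(p,q) * [l_p != l_q]

where the regional term is the negative log-likelihood of the pixel's gray
value under histogram intensity models of the marked object and background,

    R_p("obj") = -ln Pr(I_p | O),    R_p("bkg") = -ln Pr(I_p | B),

and the boundary penalty combines gray-value contrast with pixel distance,

    A(p,q) = exp(-(I_p - I_q)^2 / (2 sigma^2)) * 1 / dist(p, q).

The energy is encoded as capacities of an s-t network: each pixel is a node
with terminal edges (t-links) to the source (foreground terminal) and sink,
and neighbour edges (n-links) within a 4- or 8-connected grid.  Marked
pixels are clamped by a large finite capacity ``K`` exceeding any sum of
incident n-links, so the minimum cut equals the minimum of ``E`` subject to
the marks, and the cut capacity of any labeling equals its energy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Union

import numpy as np

from .imageio import IntensityImage

__all__ = [
    "LabelImage",
    "SeedSet",
    "IntensityModel",
    "GraphCutParams",
    "STGraph",
    "estimate_intensity_model",
    "regional_cost",
    "boundary_weight",
    "estimate_sigma",
    "build_graph",
    "labeling_energy",
    "cut_capacity",
]


@dataclass
class LabelImage:
    """Per-pixel binary labeling; 1 = foreground (bone), 0 = background."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.labels)
        if arr.ndim != 2:
            raise ValueError(f"labels must be 2-D, got shape {arr.shape}")
        if not np.isin(arr, (0, 1)).all():
            raise ValueError("labels must be 0 or 1")
        self.labels = arr.astype(np.uint8)

    @property
    def height(self) -> int:
        return self.labels.shape[0]

    @property
    def width(self) -> int:
        return self.labels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def foreground_count(self) -> int:
        return int(self.labels.sum())


@dataclass(frozen=True)
class SeedSet:
    """Manually placed object and background seed pixels.

    The two coordinate sets must be disjoint; coordinates are 0-based
    ``(row, col)`` tuples.
    """

    object_seeds: frozenset
    background_seeds: frozenset

    def __init__(self, object_seeds: Iterable, background_seeds: Iterable):
        obj = frozenset((int(r), int(c)) for r, c in object_seeds)
        bkg = frozenset((int(r), int(c)) for r, c in background_seeds)
        overlap = obj & bkg
        if overlap:
            raise ValueError(f"seed sets overlap at {sorted(overlap)[:5]}")
        object.__setattr__(self, "object_seeds", obj)
        object.__setattr__(self, "background_seeds", bkg)

    def check_bounds(self, shape: tuple[int, int]) -> None:
        h, w = shape
        for r, c in self.object_seeds | self.background_seeds:
            if not (0 <= r < h and 0 <= c < w):
                raise ValueError(f"seed ({r}, {c}) out of bounds for shape {shape}")


@dataclass
class IntensityModel:
    """Histogram likelihoods Pr(I|O) and Pr(I|B) over gray-value bins.

    Both distributions are floored at ``smoothing_eps`` and renormalized so
    every -ln probability is finite; after renormalization each probability
    is at least ``eps * (1 - bins * eps)``.
    """

    bins: int
    pr_object: np.ndarray
    pr_background: np.ndarray
    smoothing_eps: float = 1e-6

    def __post_init__(self) -> None:
        self.pr_object = np.asarray(self.pr_object, dtype=np.float64)
        self.pr_background = np.asarray(self.pr_background, dtype=np.float64)
        for name, p in (("pr_object", self.pr_object), ("pr_background", self.pr_background)):
            if p.shape != (self.bins,):
                raise ValueError(f"{name} must have shape ({self.bins},)")
            if abs(p.sum() - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1 (got {p.sum()!r})")
            floor = self.smoothing_eps * (1.0 - self.bins * self.smoothing_eps)
            if p.min() < floor:
                raise ValueError(f"{name} has probability below the smoothing floor")

    def bin_index(self, gray) -> np.ndarray:
        """Map gray values 0-255 onto equal-width histogram bins."""
        g = np.asarray(gray, dtype=np.int64)
        return g * self.bins // 256


@dataclass(frozen=True)
class GraphCutParams:
    """Tunable parameters of the energy and its graph encoding.

    Parameters
    ----------
    lam
        Weight ``lambda`` of the regional term; 0 turns segmentation into a
        pure boundary problem.
    sigma
        Gray-noise scale of the boundary penalty, or ``"auto"`` to use the
        RMS neighbour gray difference of the image (floored at 1).
    connectivity
        4 (axial neighbours) or 8 (axial + diagonal; the distance factor
        1/dist then penalizes diagonals by 1/sqrt(2)).
    bins, smoothing_eps
        Histogram resolution and probability floor of the intensity models.
    hard_seed_weight
        Terminal capacity ``K`` clamping marked pixels; ``None`` selects
        1 + the maximum over pixels of the summed incident n-link capacity,
        which no cut through n-links alone can outweigh.
    """

    lam: float = 1.0
    sigma: Union[float, Literal["auto"]] = "auto"
    connectivity: int = 8
    bins: int = 64
    smoothing_eps: float = 1e-6
    hard_seed_weight: float | None = None

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("lam must be >= 0")
        if self.sigma != "auto" and not float(self.sigma) > 0:
            raise ValueError("sigma must be > 0 or 'auto'")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if self.bins < 2:
            raise ValueError("bins must be >= 2")
        if not self.smoothing_eps > 0:
            raise ValueError("smoothing_eps must be > 0")


@dataclass
class STGraph:
    """Pixel-grid s-t network: t-link and n-link capacities.

    n-links are stored as parallel arrays ``(link_p, link_q, link_cap)``
    with each unordered neighbour pair appearing exactly once (p < q in
    row-major index).  Node ``i`` is pixel ``(i // width, i % width)``.
    """

    height: int
    width: int
    t_link_source: np.ndarray
    t_link_sink: np.ndarray
    link_p: np.ndarray
    link_q: np.ndarray
    link_cap: np.ndarray
    params: GraphCutParams

    def __post_init__(self) -> None:
        n = self.n_pixels
        for name in ("t_link_source", "t_link_sink"):
            arr = np.asarray(getattr(self, name), dtype=np.float64)
            if arr.shape != (n,):
                raise ValueError(f"{name} must have shape ({n},)")
            if not np.isfinite(arr).all() or (arr < 0).any():
                raise ValueError(f"{name} capacities must be finite and >= 0")
            setattr(self, name, arr)
        self.link_p = np.asarray(self.link_p, dtype=np.int64)
        self.link_q = np.asarray(self.link_q, dtype=np.int64)
        self.link_cap = np.asarray(self.link_cap, dtype=np.float64)
        if not (len(self.link_p) == len(self.link_q) == len(self.link_cap)):
            raise ValueError("n-link arrays must have equal length")
        if len(self.link_p) and (
            (self.link_p < 0).any()
            or (self.link_q >= n).any()
            or (self.link_p >= self.link_q).any()
        ):
            raise ValueError("n-links must satisfy 0 <= p < q < n_pixels")
        if not np.isfinite(self.link_cap).all() or (self.link_cap < 0).any():
            raise ValueError("n-link capacities must be finite and >= 0")

    @property
    def n_pixels(self) -> int:
        return self.height * self.width

    @property
    def n_links(self) -> list[tuple[int, int, float]]:
        """The n-links as ``(p, q, capacity)`` tuples."""
        return list(zip(self.link_p.tolist(), self.link_q.tolist(), self.link_cap.tolist()))

    def to_edge_list(self) -> str:
        """Plain-text debug dump: one ``p q capacity`` line per edge, with
        terminals written as ``s`` and ``t``.  Useful for reproducing solver
        failures outside the library."""
        lines = [f"# {self.height}x{self.width} grid, connectivity {self.params.connectivity}"]
        for i in range(self.n_pixels):
            lines.append(f"s {i} {float(self.t_link_source[i])!r}")
            lines.append(f"{i} t {float(self.t_link_sink[i])!r}")
        for p, q, c in zip(self.link_p, self.link_q, self.link_cap):
            lines.append(f"{int(p)} {int(q)} {float(c)!r}")
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# marker plumbing

def _marker_masks(image: IntensityImage, seeds_or_markers) -> tuple[np.ndarray, np.ndarray]:
    """Boolean (object, background) mark masks from a SeedSet or MarkerImage."""
    from .markers import MarkerClass, MarkerImage

    shape = image.shape
    if isinstance(seeds_or_markers, SeedSet):
        seeds_or_markers.check_bounds(shape)
        obj = np.zeros(shape, dtype=bool)
        bkg = np.zeros(shape, dtype=bool)
        for r, c in seeds_or_markers.object_seeds:
            obj[r, c] = True
        for r, c in seeds_or_markers.background_seeds:
            bkg[r, c] = True
        return obj, bkg
    if isinstance(seeds_or_markers, MarkerImage):
        if seeds_or_markers.shape != shape:
            raise ValueError(
                f"marker shape {seeds_or_markers.shape} != image shape {shape}"
            )
        cls = seeds_or_markers.classes
        return cls == MarkerClass.OBJECT, cls == MarkerClass.BACKGROUND
    raise TypeError(f"expected SeedSet or MarkerImage, got {type(seeds_or_markers)!r}")


# ---------------------------------------------------------------------------
# intensity model (regional term)

def estimate_intensity_model(
    image: IntensityImage,
    seeds_or_markers,
    bins: int = 64,
    smoothing_eps: float = 1e-6,
) -> IntensityModel:
    """Histogram intensity likelihoods from marked object/background pixels.

    Gray values of marked pixels are binned into ``bins`` equal-width bins
    over 0-255, normalized, floored at ``smoothing_eps`` and renormalized.

    Raises
    ------
    ValueError
        If either class has no marked pixel.
    """
    obj_mask, bkg_mask = _marker_masks(image, seeds_or_markers)
    out = {}
    for name, mask in (("object", obj_mask), ("background", bkg_mask)):
        grays = image.values[mask]
        if grays.size == 0:
            raise ValueError(f"no {name} pixels marked; both classes are required")
        idx = grays.astype(np.int64) * bins // 256
        hist = np.bincount(idx, minlength=bins).astype(np.float64)
        p = hist / hist.sum()
        p = np.maximum(p, smoothing_eps)
        out[name] = p / p.sum()
    return IntensityModel(
        bins=bins,
        pr_object=out["object"],
        pr_background=out["background"],
        smoothing_eps=smoothing_eps,
    )


def regional_cost(gray: int, model: IntensityModel, label: str) -> float:
    """Regional cost -ln Pr(I|O) or -ln Pr(I|B) of one gray value."""
    if label == "obj":
        p = model.pr_object
    elif label == "bkg":
        p = model.pr_background
    else:
        raise ValueError(f"label must be 'obj' or 'bkg', got {label!r}")
    return float(-np.log(p[int(model.bin_index(gray))]))


def _regional_cost_arrays(
    image: IntensityImage, model: IntensityModel
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized (R_obj, R_bkg) per pixel, flattened row-major."""
    idx = model.bin_index(image.values).ravel()
    return -np.log(model.pr_object[idx]), -np.log(model.pr_background[idx])


# ---------------------------------------------------------------------------
# boundary term

def boundary_weight(gray_p: float, gray_q: float, dist_pq: float, sigma: float) -> float:
    """Boundary penalty exp(-(I_p - I_q)^2 / (2 sigma^2)) / dist(p, q).

    Symmetric in p and q, strictly decreasing in |gray difference| and in
    distance; lies in ``(0, 1/dist]``.
    """
    if not dist_pq > 0:
        raise ValueError("dist_pq must be > 0")
    if not sigma > 0:
        raise ValueError("sigma must be > 0")
    d = float(gray_p) - float(gray_q)
    return float(np.exp(-(d * d) / (2.0 * sigma * sigma)) / dist_pq)


def _neighbor_pairs(
    height: int, width: int, connectivity: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All unordered neighbour pairs (p, q, dist) of a grid, p < q row-major.

    Offsets (0,1), (1,0) cover 4-connectivity; (1,1) and (1,-1) add the
    diagonals.  Each offset enumerates every pair once.
    """
    offsets = [(0, 1, 1.0), (1, 0, 1.0)]
    if connectivity == 8:
        s2 = float(np.sqrt(2.0))
        offsets += [(1, 1, s2), (1, -1, s2)]
    idx = np.arange(height * width).reshape(height, width)
    ps, qs, ds = [], [], []
    for dr, dc, dist in offsets:
        if dc >= 0:
            a = idx[: height - dr, : width - dc]
            b = idx[dr:, dc:]
        else:
            a = idx[: height - dr, -dc:]
            b = idx[dr:, :dc]
        ps.append(a.ravel())
        qs.append(b.ravel())
        ds.append(np.full(a.size, dist))
    p = np.concatenate(ps)
    q = np.concatenate(qs)
    d = np.concatenate(ds)
    lo = np.minimum(p, q)
    hi = np.maximum(p, q)
    return lo, hi, d


def _boundary_cap_array(
    image: IntensityImage, p: np.ndarray, q: np.ndarray, dist: np.ndarray, sigma: float
) -> np.ndarray:
    g = image.values.ravel().astype(np.float64)
    diff = g[p] - g[q]
    return np.exp(-(diff * diff) / (2.0 * sigma * sigma)) / dist


def estimate_sigma(image: IntensityImage, connectivity: int = 8) -> float:
    """RMS gray difference over neighbour pairs, floored at 1.

    Serves as the automatic noise scale of the boundary penalty: contrasts
    comparable to typical neighbour differences are treated as noise, much
    larger contrasts as true edges.
    """
    if image.values.size < 2:
        raise ValueError("image must have at least 2 pixels")
    p, q, _ = _neighbor_pairs(image.height, image.width, connectivity)
    g = image.values.ravel().astype(np.float64)
    diff = g[p] - g[q]
    return max(1.0, float(np.sqrt(np.mean(diff * diff))))


def resolve_sigma(image: IntensityImage, params: GraphCutParams) -> float:
    return (
        estimate_sigma(image, params.connectivity)
        if params.sigma == "auto"
        else float(params.sigma)
    )


# ---------------------------------------------------------------------------
# graph construction and energy

def build_graph(
    image: IntensityImage,
    markers,
    params: GraphCutParams | None = None,
    model: IntensityModel | None = None,
) -> STGraph:
    """Encode the segmentation energy of *image* under *markers* as an s-t graph.

    n-links carry the boundary penalty; unmarked pixels get t-links
    ``source = lam * R_p("bkg")`` and ``sink = lam * R_p("obj")`` (the cut
    severs the edge to the terminal the pixel is *not* assigned to, so a
    source-side/foreground pixel pays its object cost).  Marked pixels are
    clamped with capacity ``K`` on their class terminal and 0 on the other.

    *model* overrides the histogram estimation from *markers* — used by the
    iterated refinement, which re-estimates likelihoods from the current
    labeling while keeping the original marks hard.
    """
    if params is None:
        params = GraphCutParams()
    obj_mask, bkg_mask = _marker_masks(image, markers)
    if not obj_mask.any() or not bkg_mask.any():
        missing = "object" if not obj_mask.any() else "background"
        raise ValueError(f"markers contain no {missing} pixels; both classes are required")
    if model is None:
        model = estimate_intensity_model(image, markers, params.bins, params.smoothing_eps)
    sigma = resolve_sigma(image, params)

    p, q, dist = _neighbor_pairs(image.height, image.width, params.connectivity)
    cap = _boundary_cap_array(image, p, q, dist, sigma)

    r_obj, r_bkg = _regional_cost_arrays(image, model)
    t_source = params.lam * r_bkg
    t_sink = params.lam * r_obj

    if params.hard_seed_weight is None:
        incident = np.bincount(p, weights=cap, minlength=image.values.size)
        incident += np.bincount(q, weights=cap, minlength=image.values.size)
        hard = 1.0 + float(incident.max()) if incident.size else 1.0
    else:
        hard = float(params.hard_seed_weight)

    obj_flat = obj_mask.ravel()
    bkg_flat = bkg_mask.ravel()
    t_source[obj_flat] = hard
    t_sink[obj_flat] = 0.0
    t_source[bkg_flat] = 0.0
    t_sink[bkg_flat] = hard

    return STGraph(
        height=image.height,
        width=image.width,
        t_link_source=t_source,
        t_link_sink=t_sink,
        link_p=p,
        link_q=q,
        link_cap=cap,
        params=params,
    )


def cut_capacity(graph: STGraph, labeling: LabelImage) -> float:
    """Capacity of the s-t cut induced by *labeling* (1 = source side)."""
    if labeling.shape != (graph.height, graph.width):
        raise ValueError(
            f"labeling shape {labeling.shape} != graph grid {(graph.height, graph.width)}"
        )
    lab = labeling.labels.ravel().astype(bool)
    total = float(graph.t_link_sink[lab].sum()) + float(graph.t_link_source[~lab].sum())
    if len(graph.link_cap):
        crossing = lab[graph.link_p] != lab[graph.link_q]
        total += float(graph.link_cap[crossing].sum())
    return total


def labeling_energy(
    image: IntensityImage,
    labeling: LabelImage,
    markers,
    params: GraphCutParams | None = None,
    model: IntensityModel | None = None,
) -> float:
    """Energy E(L) of a labeling, summed directly from the model terms.

    Uses the same intensity model and boundary weights as
    :func:`build_graph` but sums the energy independently of the graph's
    capacity arrays; marked pixels contribute 0 when labeled as marked and
    the clamp weight ``K`` otherwise, so the result equals the cut capacity
    of the corresponding s-t partition.
    """
    if params is None:
        params = GraphCutParams()
    if labeling.shape != image.shape:
        raise ValueError(f"labeling shape {labeling.shape} != image shape {image.shape}")
    obj_mask, bkg_mask = _marker_masks(image, markers)
    if model is None:
        model = estimate_intensity_model(image, markers, params.bins, params.smoothing_eps)
    sigma = resolve_sigma(image, params)

    p, q, dist = _neighbor_pairs(image.height, image.width, params.connectivity)
    cap = _boundary_cap_array(image, p, q, dist, sigma)
    lab = labeling.labels.ravel().astype(bool)

    if params.hard_seed_weight is None:
        incident = np.bincount(p, weights=cap, minlength=image.values.size)
        incident += np.bincount(q, weights=cap, minlength=image.values.size)
        hard = 1.0 + float(incident.max()) if incident.size else 1.0
    else:
        hard = float(params.hard_seed_weight)

    r_obj, r_bkg = _regional_cost_arrays(image, model)
    free = ~(obj_mask.ravel() | bkg_mask.ravel())
    regional = np.where(lab, r_obj, r_bkg)
    energy = params.lam * float(regional[free].sum())
    # seed penalties: K when a marked pixel is labeled against its mark
    energy += hard * float((obj_mask.ravel() & ~lab).sum())
    energy += hard * float((bkg_mask.ravel() & lab).sum())
    # boundary term over label-disagreement pairs
    if len(cap):
        energy += float(cap[lab[p] != lab[q]].sum())
    return energy
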