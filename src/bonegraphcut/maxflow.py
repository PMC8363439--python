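"""Minimum s-t cut solvers for the pixel-grid segmentation graph.

Two exact routes are provided:

* :func:`solve_min_cut` — the production solver.  Small graphs go through
  networkx's preflow-push in float arithmetic; large grids are solved by
  scipy's C max-flow after scaling capacities to integers (the scale is
  chosen per graph so the flow bound stays within the solver's 32-bit
  range).  In either case the reported ``flow_value`` is the exact float
  cut capacity of the returned partition.
* :func:`brute_force_min_cut` — exhaustive enumeration over all 2^n pixel
  labelings (n <= 16), the independent oracle used to verify the solver.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .graph_model import LabelImage, STGraph, cut_capacity

__all__ = ["CutResult", "solve_min_cut", "brute_force_min_cut", "write_debug_dump"]

# below this many pixels the exact float path is used; grids beyond it are
# solved by the scaled-integer C path
_EXACT_PATH_MAX_PIXELS = 2048

# scipy.sparse.csgraph.maximum_flow wraps above 2**31 regardless of the
# input dtype, so scaled capacities must keep the total flow below this
_INT_FLOW_LIMIT = 2**31 - 1


@dataclass
class CutResult:
    """A minimum cut: its capacity and the induced labeling (source side = 1)."""

    flow_value: float
    labeling: LabelImage

    def __post_init__(self) -> None:
        if self.flow_value < 0:
            raise ValueError("flow_value must be >= 0")


def _validate(graph: STGraph) -> None:
    if not isinstance(graph, STGraph):
        raise TypeError(f"expected STGraph, got {type(graph)!r}")
    # STGraph.__post_init__ already enforces capacity and index invariants;
    # re-check the cheap ones in case arrays were mutated in place.
    for arr in (graph.t_link_source, graph.t_link_sink, graph.link_cap):
        if (np.asarray(arr) < 0).any() or not np.isfinite(arr).all():
            raise ValueError("graph capacities must be finite and >= 0")
    if len(graph.link_p) and int(graph.link_q.max(initial=0)) >= graph.n_pixels:
        raise ValueError("n-link endpoint out of range")


def _labeling_from_source_side(graph: STGraph, source_side: np.ndarray) -> LabelImage:
    return LabelImage(source_side.reshape(graph.height, graph.width).astype(np.uint8))


def _solve_networkx(graph: STGraph) -> np.ndarray:
    import networkx as nx
    from networkx.algorithms.flow import preflow_push

    G = nx.DiGraph()
    n = graph.n_pixels
    src, snk = n, n + 1
    for i in range(n):
        if graph.t_link_source[i] > 0:
            G.add_edge(src, i, capacity=float(graph.t_link_source[i]))
        if graph.t_link_sink[i] > 0:
            G.add_edge(i, snk, capacity=float(graph.t_link_sink[i]))
    for p, q, c in zip(graph.link_p, graph.link_q, graph.link_cap):
        if c > 0:
            G.add_edge(int(p), int(q), capacity=float(c))
            G.add_edge(int(q), int(p), capacity=float(c))
    G.add_node(src)
    G.add_node(snk)
    _, (s_side, _) = nx.minimum_cut(G, src, snk, flow_func=preflow_push)
    source_side = np.zeros(n, dtype=bool)
    for node in s_side:
        if node < n:
            source_side[node] = True
    return source_side


def _solve_scipy(graph: STGraph) -> np.ndarray:
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import breadth_first_order, maximum_flow

    n = graph.n_pixels
    src, snk = n, n + 1
    flow_bound = min(float(graph.t_link_source.sum()), float(graph.t_link_sink.sum()))
    # headroom n+2 covers the +0.5 rounding of every saturated terminal edge
    scale = max(1, int((_INT_FLOW_LIMIT - n - 2) / (flow_bound + 1.0)))

    pix = np.arange(n)
    rows = np.concatenate([np.full(n, src), pix, graph.link_p, graph.link_q])
    cols = np.concatenate([pix, np.full(n, snk), graph.link_q, graph.link_p])
    caps = np.concatenate(
        [graph.t_link_source, graph.t_link_sink, graph.link_cap, graph.link_cap]
    )
    data = np.rint(caps * scale).astype(np.int64)
    keep = data > 0
    mat = csr_matrix(
        (data[keep], (rows[keep], cols[keep])), shape=(n + 2, n + 2), dtype=np.int64
    )
    res = maximum_flow(mat, src, snk)
    residual = mat - res.flow
    residual.data = (residual.data > 0).astype(np.int64)
    residual.eliminate_zeros()
    order = breadth_first_order(residual, src, directed=True, return_predecessors=False)
    source_side = np.zeros(n, dtype=bool)
    reachable = order[order < n]
    source_side[reachable] = True
    return source_side


def solve_min_cut(graph: STGraph) -> CutResult:
    """Exact minimum s-t cut of *graph*.

    Returns the labeling of the source-side partition (foreground = 1) and
    its cut capacity, which equals the maximum flow.  Deterministic for a
    fixed graph (row-major node ordering).
    """
    _validate(graph)
    if graph.n_pixels <= _EXACT_PATH_MAX_PIXELS:
        source_side = _solve_networkx(graph)
    else:
        source_side = _solve_scipy(graph)
    labeling = _labeling_from_source_side(graph, source_side)
    return CutResult(flow_value=cut_capacity(graph, labeling), labeling=labeling)


def brute_force_min_cut(graph: STGraph) -> CutResult:
    """Minimum cut by exhaustive enumeration of all 2^n labelings.

    Only for tiny graphs (n_pixels <= 16).  Ties are broken toward the
    labeling that is smallest in row-major binary order (pixel 0 the most
    significant bit), i.e. the first minimum encountered counting up from
    the all-background labeling.
    """
    _validate(graph)
    n = graph.n_pixels
    if n > 16:
        raise ValueError(f"brute force limited to 16 pixels, got {n}")
    m = np.arange(2**n, dtype=np.uint32)
    # bit (n-1-i) of m = label of pixel i -> integer order == lexicographic
    shifts = (n - 1) - np.arange(n)
    labelings = ((m[:, None] >> shifts[None, :]) & 1).astype(bool)
    costs = labelings @ graph.t_link_sink + (~labelings) @ graph.t_link_source
    if len(graph.link_cap):
        crossing = labelings[:, graph.link_p] != labelings[:, graph.link_q]
        costs = costs + crossing @ graph.link_cap
    best = int(np.argmin(costs))  # argmin returns the first minimum
    labeling = _labeling_from_source_side(graph, labelings[best])
    return CutResult(flow_value=float(costs[best]), labeling=labeling)


def write_debug_dump(graph: STGraph, path) -> None:
    """Write the graph as a plain-text edge list for failure reproduction."""
    Path(path).write_text(graph.to_edge_list())
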