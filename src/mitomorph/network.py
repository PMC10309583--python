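"""Skeleton-based mitochondrial network metrics for the soma compartment.

The thresholded mitochondrial mask is thinned to a one-pixel skeleton, the
skeleton is decomposed into branches (maximal paths between endpoints and
junctions), and four summary metrics are reported:

* **footprint** — total thresholded mitochondrial area (µm²);
* **mean branch length** — mean geodesic length over all branches;
* **mean summed branch length** — mean, over independent structures
  (skeleton connected components), of the summed branch length;
* **mean network branches** — mean branch count per independent structure.

Branch geodesic length sums pixel steps (diagonal steps count √2 pixels).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from skimage import morphology

__all__ = ["MinaMetrics", "SkeletonGraph", "mina_metrics", "skeleton_graph"]

_SQRT2 = float(np.sqrt(2.0))


@dataclass
class SkeletonGraph:
    """Branch decomposition of a 2D skeleton.

    ``branches`` holds one pixel-path per branch as an ``(n, 2)`` array of
    ``(y, x)`` indices; ``branch_lengths_um`` the geodesic length of each;
    ``branch_component`` the index of the connected structure each branch
    belongs to; ``n_components`` the number of independent structures
    (including branchless single-pixel structures).
    """

    branches: list[np.ndarray] = field(default_factory=list)
    branch_lengths_um: list[float] = field(default_factory=list)
    branch_component: list[int] = field(default_factory=list)
    n_components: int = 0


@dataclass
class MinaMetrics:
    footprint_um2: float
    mean_branch_length_um: float
    mean_summed_branch_length_um: float
    mean_network_branches: float
    n_components: int = 0
    empty: bool = False


def _pixel_graph(skel: np.ndarray, px_um: float) -> nx.Graph:
    """8-connected graph over skeleton pixels, edge weight = step length µm."""
    g = nx.Graph()
    ys, xs = np.nonzero(skel)
    pixels = set(zip(ys.tolist(), xs.tolist()))
    g.add_nodes_from(pixels)
    for y, x in pixels:
        for dy, dx in ((0, 1), (1, 0), (1, 1), (1, -1)):
            nb = (y + dy, x + dx)
            if nb in pixels:
                w = px_um if dy == 0 or dx == 0 else _SQRT2 * px_um
                g.add_edge((y, x), nb, weight=w)
    # 8-connectivity creates spurious triangles at diagonal steps; drop the
    # diagonal edge of any triangle so paths follow the thin skeleton.
    for u, v in list(g.edges):
        if abs(u[0] - v[0]) == 1 and abs(u[1] - v[1]) == 1:
            a, b = (u[0], v[1]), (v[0], u[1])
            if g.has_edge(u, a) and g.has_edge(a, v):
                g.remove_edge(u, v)
            elif g.has_edge(u, b) and g.has_edge(b, v):
                g.remove_edge(u, v)
    return g


def _trace_branches(g: nx.Graph, px_um: float) -> SkeletonGraph:
    """Decompose a skeleton pixel graph into maximal unbranched paths."""
    sg = SkeletonGraph()
    for ci, comp in enumerate(nx.connected_components(g)):
        sg.n_components += 1
        sub = g.subgraph(comp)
        nodes = list(comp)
        if len(nodes) == 1:
            continue  # single-pixel structure: no measurable branch
        # Branch nodes: endpoints (deg 1) and junctions (deg >= 3).
        branch_nodes = [n for n in nodes if sub.degree(n) != 2]
        visited_edges: set[frozenset] = set()
        if not branch_nodes:
            # pure cycle: walk it once as a single branch
            start = nodes[0]
            cycle = nx.find_cycle(sub, source=start)
            path = [e[0] for e in cycle] + [cycle[-1][1]]
            length = sum(sub[u][v]["weight"] for u, v in zip(path[:-1], path[1:]))
            sg.branches.append(np.asarray(path))
            sg.branch_lengths_um.append(float(length))
            sg.branch_component.append(ci)
            continue
        for bn in branch_nodes:
            for nb in sub.neighbors(bn):
                if frozenset((bn, nb)) in visited_edges:
                    continue
                path = [bn, nb]
                visited_edges.add(frozenset((bn, nb)))
                while sub.degree(path[-1]) == 2:
                    prev, cur = path[-2], path[-1]
                    nxt = next(n for n in sub.neighbors(cur) if n != prev)
                    if frozenset((cur, nxt)) in visited_edges:
                        break
                    visited_edges.add(frozenset((cur, nxt)))
                    path.append(nxt)
                length = sum(
                    sub[u][v]["weight"] for u, v in zip(path[:-1], path[1:])
                )
                sg.branches.append(np.asarray(path))
                sg.branch_lengths_um.append(float(length))
                sg.branch_component.append(ci)
    return sg


def _merge_junction_clusters(g: nx.Graph) -> nx.Graph:
    """Contract 8-adjacent junction pixels into single junction nodes."""
    junctions = [n for n in g.nodes if g.degree(n) >= 3]
    jset = set(junctions)
    cluster_graph = g.subgraph(jset)
    g = g.copy()
    for cluster in nx.connected_components(cluster_graph):
        if len(cluster) < 2:
            continue
        keep, *rest = sorted(cluster)
        for r in rest:
            if g.has_node(r) and g.has_node(keep):
                g = nx.contracted_nodes(g, keep, r, self_loops=False)
    return g


def skeleton_graph(
    mask: np.ndarray, pixel_size_nm: float, prune_px: float = 2.0
) -> SkeletonGraph:
    """Skeletonize a binary mask and decompose into branches.

    Spur branches shorter than ``prune_px`` pixels (endpoint-terminated
    whiskers produced by rasterization) are removed before the final
    decomposition.
    """
    mask = np.asarray(mask, dtype=bool)
    px_um = pixel_size_nm / 1000.0
    skel = morphology.skeletonize(mask)
    g = _pixel_graph(skel, px_um)
    g = _merge_junction_clusters(g)
    if prune_px > 0:
        first = _trace_branches(g, px_um)
        for path, length in zip(first.branches, first.branch_lengths_um):
            endpoints_deg = (g.degree(tuple(path[0])), g.degree(tuple(path[-1])))
            is_spur = min(endpoints_deg) == 1 and max(endpoints_deg) >= 3
            if is_spur and length < prune_px * px_um:
                interior = [tuple(p) for p in path[:-1]] if endpoints_deg[0] == 1 else [
                    tuple(p) for p in path[1:]
                ]
                g.remove_nodes_from(
                    [n for n in interior if g.has_node(n) and g.degree(n) <= 2]
                )
    return _trace_branches(g, px_um)


def mina_metrics(mask: np.ndarray, pixel_size_nm: float, prune_px: float = 2.0) -> MinaMetrics:
    """Compute skeleton-network metrics of a binary mitochondrial mask.

    The mask is expected to be cleaned to the soma ROI.  An empty mask yields
    all-zero metrics with ``empty=True`` and a warning.
    """
    mask = np.asarray(mask, dtype=bool)
    px_um = pixel_size_nm / 1000.0
    footprint = float(mask.sum()) * px_um * px_um
    if not mask.any():
        warnings.warn("mina_metrics: empty mask", stacklevel=2)
        return MinaMetrics(0.0, 0.0, 0.0, 0.0, n_components=0, empty=True)
    sg = skeleton_graph(mask, pixel_size_nm, prune_px=prune_px)
    if not sg.branches:
        return MinaMetrics(footprint, 0.0, 0.0, 0.0, n_components=sg.n_components)
    lengths = np.asarray(sg.branch_lengths_um)
    comp = np.asarray(sg.branch_component)
    comp_ids = np.unique(comp)
    summed = [lengths[comp == c].sum() for c in comp_ids]
    counts = [int((comp == c).sum()) for c in comp_ids]
    return MinaMetrics(
        footprint_um2=footprint,
        mean_branch_length_um=float(lengths.mean()),
        mean_summed_branch_length_um=float(np.mean(summed)),
        mean_network_branches=float(np.mean(counts)),
        n_components=sg.n_components,
    )
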