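"""Dendritic-tree summaries and the proximo-distal distribution of mitochondria.

The dendritic arbor is a rooted tree of nodes in physical (µm) coordinates.
Maximal unbranched paths are *branches* with a centrifugal order: the primary
apical dendrite is order I and the order increments at every bifurcation
moving distally (this is not Strahler ordering).  Each mitochondrion is
assigned to its nearest branch and scored 0–1 by its relative position along
that branch, 0 = proximal end, 1 = distal end (arclength fraction of the
centroid's projection).  Branch-order fractions are reported over a
restricted order interval (default II–V, the orders present in every cell).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats
from shapely.geometry import LineString, Point

__all__ = [
    "DendriteTree",
    "Branch",
    "BranchAssignment",
    "assign_branch_orders",
    "position_score",
    "order_fractions",
    "dendrite_summary",
    "fit_count_vs_length",
    "read_tree_json",
    "write_tree_json",
]


@dataclass
class Branch:
    """A maximal unbranched path of the tree."""

    id: int
    order: int  # centrifugal; primary dendrite = 1
    node_ids: list[int]
    length_um: float
    line: LineString


@dataclass
class BranchAssignment:
    mito_id: int
    branch_id: int | None
    order: int | None
    score: float | None
    assigned: bool
    distance_um: float


@dataclass
class DendriteTree:
    """Rooted dendritic tree: nodes ``id -> (x, y)`` µm plus parent links.

    The root is the soma attachment point.  ``branches`` is filled by
    :func:`assign_branch_orders`.
    """

    xy: dict[int, tuple[float, float]]
    parent: dict[int, int | None]
    branches: list[Branch] = field(default_factory=list)

    def __post_init__(self) -> None:
        roots = [i for i, p in self.parent.items() if p is None]
        if len(roots) != 1:
            raise ValueError(f"tree must have exactly one root, found {len(roots)}")
        self.root = roots[0]
        # cycle/forest check: every node must reach the root
        for i in self.xy:
            seen = set()
            j = i
            while j is not None:
                if j in seen:
                    raise ValueError("parent links contain a cycle")
                seen.add(j)
                j = self.parent[j]
            if self.root not in seen:
                raise ValueError(f"node {i} is not connected to the root")

    def children(self) -> dict[int, list[int]]:
        ch: dict[int, list[int]] = {i: [] for i in self.xy}
        for i, p in self.parent.items():
            if p is not None:
                ch[p].append(i)
        return ch

    def total_length_um(self) -> float:
        return float(
            sum(
                np.hypot(
                    self.xy[i][0] - self.xy[p][0], self.xy[i][1] - self.xy[p][1]
                )
                for i, p in self.parent.items()
                if p is not None
            )
        )

    def branch_points(self) -> list[int]:
        """Internal nodes where the tree bifurcates."""
        ch = self.children()
        return [i for i, c in ch.items() if len(c) >= 2]


def assign_branch_orders(tree: DendriteTree) -> DendriteTree:
    """Decompose the tree into branches and assign centrifugal orders.

    A branch starts at the root or at a bifurcation child and extends through
    degree-1 chains until a leaf or the next bifurcation.  Children of an
    order-k branch get order k+1.
    """
    ch = tree.children()
    tree.branches = []

    def walk(start: int, order: int) -> None:
        # a branch owns the segment connecting it to its parent bifurcation,
        # so the proximal node is the bifurcation (or root) itself
        par = tree.parent[start]
        path = ([par] if par is not None else []) + [start]
        cur = start
        while len(ch[cur]) == 1:
            cur = ch[cur][0]
            path.append(cur)
        pts = [tree.xy[i] for i in path]
        if len(pts) >= 2:
            line = LineString(pts)
            tree.branches.append(
                Branch(
                    id=len(tree.branches) + 1,
                    order=order,
                    node_ids=path,
                    length_um=float(line.length),
                    line=line,
                )
            )
        for child in ch[cur]:
            walk(child, order + 1)

    # the root's children start the primary dendrite(s) at order I; if the
    # root itself begins an unbranched chain, that chain is the primary.
    if len(ch[tree.root]) == 1:
        walk(tree.root, 1)
    else:
        for child in ch[tree.root]:
            walk(child, 1)
    return tree


def position_score(
    tree: DendriteTree,
    mito_centroid_um: tuple[float, float],
    mito_id: int = 0,
    snap_um: float = 1.0,
) -> BranchAssignment:
    """Assign a mitochondrion to its nearest branch with a 0–1 position score.

    The score is the arclength from the branch's proximal node to the
    projection of the centroid, divided by the branch length.  Centroids
    farther than ``snap_um`` from every branch are flagged unassigned.
    """
    if not tree.branches:
        assign_branch_orders(tree)
    pt = Point(mito_centroid_um)
    best: Branch | None = None
    best_d = np.inf
    for br in tree.branches:
        d = br.line.distance(pt)
        if d < best_d:
            best_d = d
            best = br
    if best is None or best_d > snap_um:
        return BranchAssignment(mito_id, None, None, None, False, float(best_d))
    score = float(best.line.project(pt)) / best.length_um
    return BranchAssignment(
        mito_id, best.id, best.order, min(max(score, 0.0), 1.0), True, float(best_d)
    )


def order_fractions(
    assignments: list[BranchAssignment], orders: tuple[int, int] = (2, 5)
) -> dict[int, float]:
    """Percentage of assigned mitochondria per branch order over ``orders``.

    Percentages are relative to the mitochondria whose order lies inside the
    (inclusive) interval, so they sum to 100 when any are present.
    """
    lo, hi = orders
    inside = [
        a for a in assignments if a.assigned and a.order is not None and lo <= a.order <= hi
    ]
    out = {k: 0.0 for k in range(lo, hi + 1)}
    if not inside:
        return out
    for a in inside:
        out[a.order] += 1
    return {k: 100.0 * v / len(inside) for k, v in out.items()}


def dendrite_summary(
    tree: DendriteTree,
    spine_segments: list[tuple[int, float, int]] | None = None,
) -> tuple[float, int, float]:
    """Total dendritic length (µm), bifurcation count and spine density.

    ``spine_segments`` lists ``(branch_id, segment_length_um, n_spines)``
    records; density is expressed as spines per 10 µm of sampled dendrite.
    Returns ``(total_length_um, n_branch_points, spines_per_10um)``.
    """
    if not tree.branches:
        assign_branch_orders(tree)
    total = tree.total_length_um()
    n_bp = len(tree.branch_points())
    density = 0.0
    if spine_segments:
        known = {b.id for b in tree.branches}
        seg_len = 0.0
        n_spines = 0
        for bid, length, count in spine_segments:
            if bid not in known:
                raise KeyError(f"spine segment references unknown branch {bid}")
            seg_len += length
            n_spines += count
        if seg_len <= 0:
            raise ZeroDivisionError("total spine-segment length must be positive")
        density = 10.0 * n_spines / seg_len
    return total, n_bp, density


def fit_count_vs_length(
    cells: list[tuple[float, float]], method: str = "pearson"
) -> dict[str, float]:
    """OLS regression of per-cell mitochondrion count on dendritic length.

    Returns slope, intercept, R², the correlation coefficient (Pearson by
    default, Spearman on request) and its two-sided p-value.  A constant
    response is reported with r = 0 and p = 1, flagged degenerate.
    """
    if len(cells) < 3:
        raise ValueError("need >= 3 cells for the regression")
    x = np.asarray([c[0] for c in cells], dtype=float)
    y = np.asarray([c[1] for c in cells], dtype=float)
    if np.allclose(x, x[0]):
        raise ValueError("zero variance in dendritic length")
    res = stats.linregress(x, y)
    out = {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "r2": float(res.rvalue**2),
        "n": float(len(cells)),
        "degenerate": 0.0,
    }
    if np.allclose(y, y[0]):
        out.update({"r": 0.0, "p": 1.0, "r2": 0.0, "degenerate": 1.0})
        return out
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    out.update({"r": float(r), "p": float(p)})
    return out


# ---------------------------------------------------------------------------
# SWC-compatible JSON serialization: [id, parent, x, y, order] per node


def write_tree_json(path: str | Path, tree: DendriteTree) -> None:
    if not tree.branches:
        assign_branch_orders(tree)
    order_of_node: dict[int, int] = {}
    for br in tree.branches:
        for nid in br.node_ids:
            order_of_node.setdefault(nid, br.order)
    rows = [
        [
            int(i),
            -1 if tree.parent[i] is None else int(tree.parent[i]),
            float(tree.xy[i][0]),
            float(tree.xy[i][1]),
            int(order_of_node.get(i, 0)),
        ]
        for i in sorted(tree.xy)
    ]
    Path(path).write_text(json.dumps({"columns": ["id", "parent", "x", "y", "order"], "nodes": rows}))


def read_tree_json(path: str | Path) -> DendriteTree:
    payload = json.loads(Path(path).read_text())
    xy: dict[int, tuple[float, float]] = {}
    parent: dict[int, int | None] = {}
    for i, p, x, y, _order in payload["nodes"]:
        xy[int(i)] = (float(x), float(y))
        parent[int(i)] = None if p == -1 else int(p)
    return DendriteTree(xy=xy, parent=parent)
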