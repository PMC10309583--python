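"""Synthetic adult-born granule neurons with known mitochondrial ground truth.

The generator builds a 2D cell geometry — a circular soma carrying a dense
mitochondrial network, and a branched dendritic arbor (centrifugal orders
I..N) carrying discrete rod-like mitochondria — then renders it into a
calibrated multi-channel 3D stack with Gaussian PSF blur, Poisson shot
noise, Gaussian read noise and a shallow background gradient.  Everything
the analysis pipeline later estimates (counts, lengths, occupancies,
co-stain intensity, lysosome overlap) is recorded exactly at generation
time, so recovery can be scored against truth.

Trees are generated in 2D because the analysis operates on maximum
z-projections; the z axis exists only for rendering.  Mitochondria are
spherocylinders (capsules) of fixed diameter whose *length* is the tip-to-tip
extent along the dendrite — the quantity a manual trace of the organelle
measures.  Placement guarantees a clearance between every pair of rods and
the soma network, so connected-component counting has an exact truth.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import LineString, Point, Polygon
from shapely.ops import substring, unary_union

from .dendrite import DendriteTree, assign_branch_orders, write_tree_json
from .io import ImageStack, RegionOfInterest, write_rois, write_stack

__all__ = [
    "NeuronSpec",
    "RenderConfig",
    "GroundTruth",
    "RenderedTruth",
    "generate_neuron",
    "render_stack",
    "generate_cohort",
]


# ---------------------------------------------------------------------------
# parameterization


@dataclass(frozen=True)
class NeuronSpec:
    """Geometric and biological parameters of one simulated neuron.

    Defaults emulate a young adult-born granule neuron: ~10 µm soma with a
    densely filled mitochondrial network, a single apical dendrite branching
    into orders up to V, and rod-shaped dendritic mitochondria whose lengths
    follow a lognormal distribution centred between the "fragmented" and
    "elongated" classes.
    """

    soma_radius_um: float = 5.0
    primary_dendrite_length_um: float = 20.0
    max_branch_order: int = 5
    branch_prob_per_order: tuple[float, ...] = (1.0, 0.9, 0.7, 0.5, 0.0)
    mean_branch_length_um: float = 18.0
    mito_linear_density_per_um: float = 0.25
    mito_length_dist: tuple[str, dict] = (
        "lognormal",
        None,  # replaced by {"median_um": 1.3, "sigma": 0.45} in __post_init__
    )
    mito_diameter_um: float = 0.4
    #: sampled lengths are floored here: rods shorter than their own diameter
    #: degenerate to sub-resolution spheres no imaging pipeline can count
    mito_min_length_um: float = 0.5
    mito_min_gap_um: float = 0.35
    dendrite_radius_um: float = 0.55
    soma_mito_fill_fraction: float = 0.55
    costain_mean_intensity: float = 120.0
    lysosome_overlap_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.mito_length_dist[1] is None:
            object.__setattr__(
                self,
                "mito_length_dist",
                ("lognormal", {"median_um": 1.3, "sigma": 0.45}),
            )
        for name in (
            "soma_radius_um",
            "primary_dendrite_length_um",
            "mean_branch_length_um",
            "mito_diameter_um",
            "dendrite_radius_um",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name}: must be > 0, got {getattr(self, name)}")
        if self.max_branch_order < 1:
            raise ValueError(f"max_branch_order: must be >= 1, got {self.max_branch_order}")
        if any(not 0.0 <= p <= 1.0 for p in self.branch_prob_per_order):
            raise ValueError("branch_prob_per_order: probabilities must lie in [0, 1]")
        if self.mito_linear_density_per_um < 0:
            raise ValueError("mito_linear_density_per_um: must be >= 0")
        if self.mito_min_length_um <= 0:
            raise ValueError("mito_min_length_um: must be > 0")
        if not 0.0 < self.soma_mito_fill_fraction <= 1.0:
            raise ValueError("soma_mito_fill_fraction: must be in (0, 1]")
        if self.costain_mean_intensity < 0:
            raise ValueError("costain_mean_intensity: must be >= 0")
        if not 0.0 <= self.lysosome_overlap_fraction <= 1.0:
            raise ValueError("lysosome_overlap_fraction: must be in [0, 1]")
        _validate_length_dist(self.mito_length_dist)


def _validate_length_dist(dist: tuple[str, dict]) -> None:
    name, params = dist
    if name == "point":
        if params.get("value_um", 0) <= 0:
            raise ValueError("mito_length_dist: point mass must be > 0")
    elif name == "lognormal":
        if params.get("median_um", 0) <= 0 or params.get("sigma", -1) < 0:
            raise ValueError("mito_length_dist: lognormal needs median_um > 0, sigma >= 0")
    elif name == "uniform":
        lo, hi = params.get("low_um", 0), params.get("high_um", 0)
        if not 0 < lo <= hi:
            raise ValueError("mito_length_dist: uniform needs 0 < low_um <= high_um")
    else:
        raise ValueError(f"mito_length_dist: unknown distribution {name!r}")


def _sample_lengths(dist: tuple[str, dict], rng: np.random.Generator, n: int) -> np.ndarray:
    name, params = dist
    if name == "point":
        return np.full(n, float(params["value_um"]))
    if name == "lognormal":
        return rng.lognormal(math.log(params["median_um"]), params["sigma"], n)
    if name == "uniform":
        return rng.uniform(params["low_um"], params["high_um"], n)
    raise ValueError(name)


@dataclass(frozen=True)
class RenderConfig:
    """Imaging model: calibration, PSF, noise and channel amplitudes.

    The default voxel matches a 63×/1.4 NA confocal acquisition with 2×
    zoom (133.6 × 133.6 nm laterally, 395.2 nm optical step).  ``photon_scale``
    sets shot-noise strength: the expected image is multiplied by it, Poisson
    sampled and divided back, so larger values mean cleaner images
    (``inf`` disables shot noise).
    """

    voxel_size_nm: tuple[float, float, float] = (133.6, 133.6, 395.2)
    psf_sigma_um: tuple[float, float] = (0.17, 0.5)  # (lateral, axial)
    background_level: float = 10.0
    background_gradient: float = 2.0
    photon_scale: float = 5.0
    read_noise_sd: float = 1.5
    bit_depth: int = 8
    seed: int = 0
    n_z: int = 7
    margin_um: float = 3.0
    cyto_amplitude: float = 60.0
    mito_amplitude: float = 160.0
    lyso_amplitude: float = 140.0
    include_costain: bool = False
    include_lysosome: bool = False
    max_voxels: int = 2**27

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.voxel_size_nm):
            raise ValueError("voxel_size_nm: all axes must be > 0")
        if self.bit_depth not in (8, 16):
            raise ValueError(f"bit_depth: must be 8 or 16, got {self.bit_depth}")
        if self.n_z < 1:
            raise ValueError("n_z: must be >= 1")


# ---------------------------------------------------------------------------
# geometry generation


@dataclass
class GroundTruth:
    """Exact record of one generated neuron.

    ``mito_table`` has one row per dendritic mitochondrion: id, branch_id,
    branch order, 0–1 position score of the centerline midpoint, true length
    (µm), centroid and endpoints in µm.  Coordinates use the cell frame:
    soma centred at the origin, µm units.
    """

    spec: NeuronSpec
    seed: int
    tree: DendriteTree
    mito_table: pd.DataFrame
    mito_lines: list[LineString]
    soma_center_um: tuple[float, float]
    soma_segments: list[LineString]
    true_soma_fill_fraction: float
    true_costain_intensity: float
    true_overlap_fraction: float | None = None

    def total_dendrite_length_um(self) -> float:
        return self.tree.total_length_um()

    def true_linear_density_per_um(self) -> float:
        return len(self.mito_table) / self.total_dendrite_length_um()

    def true_linear_occupancy_pct(self) -> float:
        return 100.0 * self.mito_table["length_um"].sum() / self.total_dendrite_length_um()


def _grow_tree(spec: NeuronSpec, rng: np.random.Generator) -> DendriteTree:
    """Recursive 2D arbor: order-I primary dendrite, bifurcations thereafter."""
    xy: dict[int, tuple[float, float]] = {}
    parent: dict[int, int | None] = {}
    counter = [0]

    def add_node(pos: tuple[float, float], par: int | None) -> int:
        counter[0] += 1
        nid = counter[0]
        xy[nid] = (float(pos[0]), float(pos[1]))
        parent[nid] = par
        return nid

    root = add_node((0.0, spec.soma_radius_um), None)

    def grow(node: int, direction: float, length: float, order: int) -> None:
        # each branch is a 3-segment polyline with small heading jitter
        cur = node
        heading = direction
        for frac in (0.34, 0.33, 0.33):
            heading += rng.normal(0.0, 0.08)
            step = frac * length
            x, y = xy[cur]
            cur = add_node((x + step * math.sin(heading), y + step * math.cos(heading)), cur)
        p_idx = min(order, len(spec.branch_prob_per_order)) - 1
        p_branch = spec.branch_prob_per_order[p_idx]
        if order < spec.max_branch_order and rng.random() < p_branch:
            spread = rng.uniform(0.35, 0.6)
            for sign in (-1.0, 1.0):
                child_len = max(
                    2.0, rng.normal(spec.mean_branch_length_um, 0.25 * spec.mean_branch_length_um)
                )
                grow(cur, heading + sign * spread, child_len, order + 1)

    grow(root, 0.0, spec.primary_dendrite_length_um, 1)
    tree = DendriteTree(xy=xy, parent=parent)
    return assign_branch_orders(tree)


def _place_mitochondria(
    spec: NeuronSpec,
    tree: DendriteTree,
    soma_segments: list[LineString],
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, list[LineString]]:
    """Poisson placement of non-overlapping capsules along every branch.

    Per branch the target count is Poisson(density × branch length).  A
    rod's *length* is its tip-to-tip extent along the branch (what a manual
    trace of the organelle measures); the rendered capsule's centerline is
    the extent shortened by half a diameter at each end so the drawn shape
    spans exactly that extent.  Each center is sampled uniformly from the
    exact free arclength left by previously placed rods (a hard-core process
    with a minimum tip gap), so rods are only lost when a branch is truly
    saturated and the realized linear density tracks the parameter closely.
    Cross-branch and soma-network conflicts are resolved by resampling.
    """
    clearance = spec.mito_diameter_um + spec.mito_min_gap_um
    rows = []
    lines: list[LineString] = []
    placed: list[LineString] = []
    mito_id = 0
    for br in tree.branches:
        lb = br.length_um
        n = rng.poisson(spec.mito_linear_density_per_um * lb)
        if n == 0:
            continue
        lengths = _sample_lengths(spec.mito_length_dist, rng, n)
        lengths = np.sort(np.maximum(lengths, spec.mito_min_length_um))[::-1]
        occupied: list[tuple[float, float]] = []  # (center, extent)
        for length in lengths:
            if length >= lb:
                continue  # rod longer than its branch: skip
            width = min(spec.mito_diameter_um, length)
            half_w = width / 2
            ok = None
            for _ in range(30):
                c = _sample_free_center(occupied, length, spec.mito_min_gap_um, lb, rng)
                if c is None:
                    break
                lo, hi = c - length / 2, c + length / 2
                # centerline retracted by half a width per tip; rods no
                # longer than their width degenerate to a point (sphere)
                s0, s1 = lo + half_w, hi - half_w
                if s1 > s0:
                    seg = substring(br.line, s0, s1)
                else:
                    seg = br.line.interpolate(c)
                if any(seg.distance(s) < clearance for s in soma_segments):
                    continue
                if any(seg.distance(other) < clearance for other in placed):
                    continue
                ok = (c, seg)
                break
            if ok is None:
                continue
            c, seg = ok
            occupied.append((c, length))
            placed.append(seg)
            mito_id += 1
            lo, hi = c - length / 2, c + length / 2
            mid = br.line.interpolate(c)
            p0, p1 = br.line.interpolate(lo), br.line.interpolate(hi)
            rows.append(
                {
                    "id": mito_id,
                    "branch_id": br.id,
                    "order": br.order,
                    "score": c / lb,
                    "length_um": float(length),
                    "width_um": float(width),
                    "cx_um": mid.x,
                    "cy_um": mid.y,
                    "x0_um": p0.x,
                    "y0_um": p0.y,
                    "x1_um": p1.x,
                    "y1_um": p1.y,
                }
            )
            lines.append(seg)
    columns = [
        "id", "branch_id", "order", "score", "length_um", "width_um",
        "cx_um", "cy_um", "x0_um", "y0_um", "x1_um", "y1_um",
    ]
    return pd.DataFrame(rows, columns=columns), lines


def _sample_free_center(
    occupied: list[tuple[float, float]],
    extent: float,
    gap: float,
    lb: float,
    rng: np.random.Generator,
) -> float | None:
    """Uniform sample over the free center positions along one branch.

    A new rod of ``extent`` centred at ``c`` conflicts with an occupied rod
    ``(c_i, e_i)`` when ``|c - c_i| < (extent + e_i)/2 + gap``.  The feasible
    set is ``[extent/2, lb - extent/2]`` minus those blocked intervals;
    returns ``None`` when it has measure zero.
    """
    lo, hi = extent / 2, lb - extent / 2
    if hi <= lo:
        return None
    blocked = sorted(
        (c - (extent + e) / 2 - gap, c + (extent + e) / 2 + gap) for c, e in occupied
    )
    free: list[tuple[float, float]] = []
    cur = lo
    for a, b in blocked:
        if b <= cur:
            continue
        if a > hi:
            break
        if a > cur:
            free.append((cur, min(a, hi)))
        cur = max(cur, b)
        if cur >= hi:
            break
    if cur < hi:
        free.append((cur, hi))
    total = sum(b - a for a, b in free)
    if total <= 0:
        return None
    u = rng.uniform(0, total)
    for a, b in free:
        if u <= b - a:
            return a + u
        u -= b - a
    return free[-1][1]


def _fill_soma_network(
    spec: NeuronSpec, rng: np.random.Generator, max_segments: int = 400
) -> tuple[list[LineString], float]:
    """Random geometric network inside the soma disc, grown to a fill target.

    Points are sampled uniformly in the disc and connected to their nearest
    predecessor; segments buffered to rod diameter accumulate until the
    covered fraction reaches ``soma_mito_fill_fraction``.
    """
    r = spec.soma_radius_um
    # covered-area bookkeeping on a fine internal grid (20 px/µm)
    res = 0.05
    n = int(math.ceil(2 * r / res)) + 1
    ax = -r + np.arange(n) * res
    gx, gy = np.meshgrid(ax, ax)
    in_disc = gx**2 + gy**2 <= r**2
    covered = np.zeros((n, n), dtype=bool)
    target_px = spec.soma_mito_fill_fraction * in_disc.sum()
    half_w = spec.mito_diameter_um / 2

    def sample_point() -> tuple[float, float]:
        rr = (r - half_w) * math.sqrt(rng.random())
        th = rng.uniform(0, 2 * math.pi)
        return (rr * math.cos(th), rr * math.sin(th))

    def stamp(seg: LineString) -> None:
        minx, miny, maxx, maxy = seg.bounds
        i0 = max(int((miny - half_w + r) / res) - 1, 0)
        i1 = min(int((maxy + half_w + r) / res) + 2, n)
        j0 = max(int((minx - half_w + r) / res) - 1, 0)
        j1 = min(int((maxx + half_w + r) / res) + 2, n)
        sub_x, sub_y = gx[i0:i1, j0:j1], gy[i0:i1, j0:j1]
        d = _point_segment_dist(sub_x, sub_y, seg)
        covered[i0:i1, j0:j1] |= d <= half_w

    pts = np.array([sample_point()])
    segs: list[LineString] = []
    while len(segs) < max_segments:
        p = sample_point()
        d2 = np.sum((pts - p) ** 2, axis=1)
        q = pts[np.argmin(d2)]
        if d2.min() < 0.04:
            continue
        pts = np.vstack([pts, p])
        seg = LineString([tuple(q), p])
        segs.append(seg)
        stamp(seg)
        if (covered & in_disc).sum() >= target_px:
            break
    fill = float((covered & in_disc).sum() / max(in_disc.sum(), 1))
    return segs, fill


def _point_segment_dist(px: np.ndarray, py: np.ndarray, seg: LineString) -> np.ndarray:
    (x0, y0), (x1, y1) = seg.coords
    dx, dy = x1 - x0, y1 - y0
    denom = dx * dx + dy * dy
    if denom == 0:
        return np.hypot(px - x0, py - y0)
    t = np.clip(((px - x0) * dx + (py - y0) * dy) / denom, 0.0, 1.0)
    return np.hypot(px - (x0 + t * dx), py - (y0 + t * dy))


def generate_neuron(spec: NeuronSpec, seed: int) -> GroundTruth:
    """Generate one neuron geometry with exact mitochondrial ground truth.

    Deterministic given ``(spec, seed)``.  Raises ``ValueError`` naming the
    offending field for invalid specs (validation happens in ``NeuronSpec``).
    """
    rng = np.random.default_rng(seed)
    tree = _grow_tree(spec, rng)
    soma_segments, fill = _fill_soma_network(spec, rng)
    mito_table, mito_lines = _place_mitochondria(spec, tree, soma_segments, rng)
    return GroundTruth(
        spec=spec,
        seed=int(seed),
        tree=tree,
        mito_table=mito_table,
        mito_lines=mito_lines,
        soma_center_um=(0.0, 0.0),
        soma_segments=soma_segments,
        true_soma_fill_fraction=fill,
        true_costain_intensity=spec.costain_mean_intensity,
    )


# ---------------------------------------------------------------------------
# rendering


@dataclass
class RenderedTruth:
    """Pixel-level truth of one rendered cell.

    ``origin_um`` maps pixel ``(ix, iy)`` centers to the cell frame:
    ``x_um = origin_um[0] + ix·px_um``.  Masks are 2D ``(y, x)``; ROIs are in
    pixel coordinates, ready for the analysis pipeline.  The tree re-expressed
    in image-frame µm is available via :meth:`tree_image_frame`.
    """

    origin_um: tuple[float, float]
    px_um: float
    shape: tuple[int, int]
    cyto_mask: np.ndarray
    mito_dend_mask: np.ndarray
    mito_soma_mask: np.ndarray
    lyso_mask: np.ndarray | None
    soma_roi: RegionOfInterest
    arbor_roi: RegionOfInterest
    primary_roi: RegionOfInterest
    background_boxes: list[RegionOfInterest]
    true_soma_occupancy_pct: float
    true_arbor_occupancy_pct: float
    true_overlap_fraction: float | None
    #: expected (pre-noise) per-pixel co-stain signal averaged over the true
    #: mitochondrial mask in the max projection; the PSF attenuates this below
    #: the nominal spec intensity, so intensity recovery is scored against it
    true_costain_mean_px: float | None = None

    @property
    def mito_mask(self) -> np.ndarray:
        return self.mito_dend_mask | self.mito_soma_mask

    def to_image_frame(self, geometry: GroundTruth) -> GroundTruth:
        """Return a copy of ``geometry`` with tree/table shifted to image µm."""
        dx, dy = -self.origin_um[0], -self.origin_um[1]
        xy = {i: (x + dx, y + dy) for i, (x, y) in geometry.tree.xy.items()}
        tree = DendriteTree(xy=xy, parent=dict(geometry.tree.parent))
        assign_branch_orders(tree)
        table = geometry.mito_table.copy()
        for c in ("cx_um", "x0_um", "x1_um"):
            table[c] = table[c] + dx
        for c in ("cy_um", "y0_um", "y1_um"):
            table[c] = table[c] + dy
        return replace(geometry, tree=tree, mito_table=table)


def _paint(
    mask: np.ndarray,
    geom,
    origin: tuple[float, float],
    px_um: float,
) -> None:
    """OR pixels whose centers fall inside ``geom`` (µm) into ``mask``."""
    if geom.is_empty:
        return
    polys = getattr(geom, "geoms", [geom])
    h, w = mask.shape
    for poly in polys:
        minx, miny, maxx, maxy = poly.bounds
        x0 = max(int(math.floor((minx - origin[0]) / px_um)) - 1, 0)
        x1 = min(int(math.ceil((maxx - origin[0]) / px_um)) + 2, w)
        y0 = max(int(math.floor((miny - origin[1]) / px_um)) - 1, 0)
        y1 = min(int(math.ceil((maxy - origin[1]) / px_um)) + 2, h)
        if x0 >= x1 or y0 >= y1:
            continue
        xs = origin[0] + np.arange(x0, x1) * px_um
        ys = origin[1] + np.arange(y0, y1) * px_um
        gx, gy = np.meshgrid(xs, ys)
        shapely.prepare(poly)
        inside = shapely.contains_xy(poly, gx.ravel(), gy.ravel()).reshape(gy.shape)
        mask[y0:y1, x0:x1] |= inside


def _ring_roi(poly: Polygon, origin: tuple[float, float], px_um: float, label: str) -> RegionOfInterest:
    """Exterior ring of a µm-frame polygon as a pixel-coordinate polygon ROI."""
    poly = poly.simplify(0.25 * px_um)
    if poly.geom_type == "MultiPolygon":
        poly = max(poly.geoms, key=lambda p: p.area)
    xs, ys = poly.exterior.coords.xy
    verts = np.column_stack(
        [(np.asarray(xs) - origin[0]) / px_um, (np.asarray(ys) - origin[1]) / px_um]
    )
    if np.allclose(verts[0], verts[-1]):
        verts = verts[:-1]
    return RegionOfInterest(kind="polygon", vertices=verts, label=label)


def _find_background_boxes(
    occupied: np.ndarray, px_um: float, n_boxes: int = 3, side_um: float = 5.0
) -> list[RegionOfInterest]:
    side = int(round(side_um / px_um))
    h, w = occupied.shape
    boxes = []
    # scan a coarse grid from the corners inward for signal-free windows
    candidates = []
    step = max(side // 2, 1)
    for y in range(1, h - side - 1, step):
        for x in range(1, w - side - 1, step):
            candidates.append((y, x))
    candidates.sort(key=lambda yx: min(yx[0] + yx[1], (h - yx[0]) + (w - yx[1])))
    taken: list[tuple[int, int]] = []
    for y, x in candidates:
        if occupied[y : y + side, x : x + side].any():
            continue
        if any(abs(y - ty) < side and abs(x - tx) < side for ty, tx in taken):
            continue
        taken.append((y, x))
        boxes.append(
            RegionOfInterest(
                kind="box",
                vertices=np.array(
                    [[x, y], [x + side, y], [x + side, y + side], [x, y + side]],
                    dtype=float,
                ),
                label="background",
            )
        )
        if len(boxes) == n_boxes:
            return boxes
    raise RuntimeError("could not place three signal-free background boxes")


def _rasterize(geometry: GroundTruth, cfg: RenderConfig) -> RenderedTruth:
    spec = geometry.spec
    px_um = cfg.voxel_size_nm[0] / 1000.0
    soma_disc = Point(geometry.soma_center_um).buffer(spec.soma_radius_um, quad_segs=64)
    branch_lines = [br.line for br in geometry.tree.branches]
    dend_tube = unary_union([l.buffer(spec.dendrite_radius_um) for l in branch_lines])

    all_geoms = [soma_disc, dend_tube] + [l.buffer(spec.mito_diameter_um / 2) for l in geometry.mito_lines]
    minx = min(g.bounds[0] for g in all_geoms) - cfg.margin_um
    miny = min(g.bounds[1] for g in all_geoms) - cfg.margin_um
    maxx = max(g.bounds[2] for g in all_geoms) + cfg.margin_um
    maxy = max(g.bounds[3] for g in all_geoms) + cfg.margin_um
    w = int(math.ceil((maxx - minx) / px_um))
    h = int(math.ceil((maxy - miny) / px_um))
    n_channels = 2 + int(cfg.include_costain) + int(cfg.include_lysosome)
    if h * w * cfg.n_z * n_channels > cfg.max_voxels:
        raise ValueError(
            f"stack of {h}x{w}x{cfg.n_z}x{n_channels} voxels exceeds the "
            f"max_voxels budget ({cfg.max_voxels})"
        )
    origin = (float(minx), float(miny))

    cyto = np.zeros((h, w), dtype=bool)
    _paint(cyto, soma_disc, origin, px_um)
    _paint(cyto, dend_tube, origin, px_um)

    mito_dend = np.zeros((h, w), dtype=bool)
    mito_widths = geometry.mito_table["width_um"].to_numpy() if len(geometry.mito_table) else []
    for line, mw in zip(geometry.mito_lines, mito_widths):
        _paint(mito_dend, line.buffer(mw / 2, quad_segs=16), origin, px_um)

    mito_soma = np.zeros((h, w), dtype=bool)
    soma_net = unary_union(
        [s.buffer(spec.mito_diameter_um / 2) for s in geometry.soma_segments]
    ).intersection(soma_disc)
    _paint(mito_soma, soma_net, origin, px_um)

    soma_mask = np.zeros((h, w), dtype=bool)
    _paint(soma_mask, soma_disc, origin, px_um)

    soma_roi = _ring_roi(soma_disc, origin, px_um, "soma")
    primary_line = next(br.line for br in geometry.tree.branches if br.order == 1)
    primary_roi = _ring_roi(
        primary_line.buffer(spec.dendrite_radius_um + 0.3), origin, px_um, "primary_dendrite"
    )
    arbor_poly = unary_union(
        [l.buffer(spec.dendrite_radius_um + 0.8) for l in branch_lines]
    ).difference(soma_disc.buffer(0.4))
    arbor_roi = _ring_roi(arbor_poly, origin, px_um, "arbor")

    lyso = None
    true_overlap = None
    if cfg.include_lysosome:
        lyso, true_overlap = _make_lysosome_mask(geometry, cfg, mito_dend | mito_soma, cyto, origin, px_um)

    soma_px = int(soma_mask.sum())
    arbor_mask = np.zeros((h, w), dtype=bool)
    from .io import polygon_mask  # local import to avoid cycle at module load

    arbor_mask = polygon_mask(arbor_roi, (h, w))
    arbor_px = max(int(arbor_mask.sum()), 1)

    return RenderedTruth(
        origin_um=origin,
        px_um=px_um,
        shape=(h, w),
        cyto_mask=cyto,
        mito_dend_mask=mito_dend,
        mito_soma_mask=mito_soma,
        lyso_mask=lyso,
        soma_roi=soma_roi,
        arbor_roi=arbor_roi,
        primary_roi=primary_roi,
        background_boxes=_find_background_boxes(cyto | mito_dend | mito_soma, px_um),
        true_soma_occupancy_pct=100.0 * float((mito_soma & soma_mask).sum()) / max(soma_px, 1),
        true_arbor_occupancy_pct=100.0 * float((mito_dend & arbor_mask).sum()) / arbor_px,
        true_overlap_fraction=true_overlap,
    )


def _make_lysosome_mask(
    geometry: GroundTruth,
    cfg: RenderConfig,
    mito_mask: np.ndarray,
    cyto_mask: np.ndarray,
    origin: tuple[float, float],
    px_um: float,
) -> tuple[np.ndarray, float]:
    """Grow lysosome-like puncta until the mito-overlap target is reached.

    Discs (~0.35 µm radius) are seeded on random mitochondrial pixels until
    overlap_area/mito_area reaches the configured target, then an equal number of
    non-overlapping cytoplasmic puncta are added as free lysosomes.
    """
    rng = np.random.default_rng(cfg.seed + 101)
    target = geometry.spec.lysosome_overlap_fraction
    lyso = np.zeros_like(mito_mask)
    mito_px = max(int(mito_mask.sum()), 1)
    disc_r_px = max(int(round(0.35 / px_um)), 1)
    ys, xs = np.nonzero(mito_mask)
    n_on = 0
    yy, xx = np.ogrid[-disc_r_px : disc_r_px + 1, -disc_r_px : disc_r_px + 1]
    disc = yy**2 + xx**2 <= disc_r_px**2

    def stamp(cy: int, cx: int) -> None:
        y0, y1 = cy - disc_r_px, cy + disc_r_px + 1
        x0, x1 = cx - disc_r_px, cx + disc_r_px + 1
        if y0 < 0 or x0 < 0 or y1 > lyso.shape[0] or x1 > lyso.shape[1]:
            return
        lyso[y0:y1, x0:x1] |= disc

    for _ in range(20000):
        if float((lyso & mito_mask).sum()) / mito_px >= target:
            break
        if len(ys) == 0:
            break
        k = rng.integers(len(ys))
        stamp(int(ys[k]), int(xs[k]))
        n_on += 1
    from scipy import ndimage

    # free lysosomes stay clear of the mitochondrial mask so they do not
    # perturb the achieved overlap fraction
    keepout = ndimage.binary_dilation(mito_mask, iterations=disc_r_px + 1)
    free = cyto_mask & ~keepout
    fys, fxs = np.nonzero(free)
    for _ in range(max(n_on // 2, 3)):
        if len(fys) == 0:
            break
        k = rng.integers(len(fys))
        stamp(int(fys[k]), int(fxs[k]))
    achieved = float((lyso & mito_mask).sum()) / mito_px
    return lyso, achieved


def render_stack(
    geometry: GroundTruth, cfg: RenderConfig
) -> tuple[ImageStack, RenderedTruth]:
    """Render a neuron geometry into a calibrated multi-channel stack.

    Channels: ``cyto`` (cytoplasmic fill), ``mito`` (mitochondrial rods and
    soma network), optional ``costain`` (signal restricted to mitochondria at
    the configured mean intensity) and ``lyso``.  Structures live on the central
    optical section and are blurred by a 3D Gaussian PSF; background and
    noise are then applied per the config.  Deterministic given
    ``(geometry, cfg)``.
    """
    truth = _rasterize(geometry, cfg)
    rng = np.random.default_rng(cfg.seed)
    px_um = truth.px_um
    pz_um = cfg.voxel_size_nm[2] / 1000.0
    h, w = truth.shape
    zc = cfg.n_z // 2
    sig_xy = cfg.psf_sigma_um[0] / px_um
    sig_z = cfg.psf_sigma_um[1] / pz_um if cfg.n_z > 1 else 0.0

    names = ["cyto", "mito"]
    planes = [
        truth.cyto_mask.astype(np.float64) * cfg.cyto_amplitude,
        truth.mito_mask.astype(np.float64) * cfg.mito_amplitude,
    ]
    if cfg.include_costain:
        names.append("costain")
        planes.append(truth.mito_mask.astype(np.float64) * geometry.spec.costain_mean_intensity)
    if cfg.include_lysosome:
        names.append("lyso")
        planes.append(truth.lyso_mask.astype(np.float64) * cfg.lyso_amplitude)

    from scipy import ndimage

    max_val = float(2**cfg.bit_depth - 1)
    channels = []
    # shallow left-to-right illumination gradient on top of a flat offset
    ramp = cfg.background_level + cfg.background_gradient * (
        np.arange(w, dtype=float) / max(w - 1, 1) - 0.5
    )
    bg = np.broadcast_to(ramp, (h, w))
    for name, plane in zip(names, planes):
        vol = np.zeros((cfg.n_z, h, w), dtype=np.float64)
        vol[zc] = plane
        if sig_xy > 0 or sig_z > 0:
            vol = ndimage.gaussian_filter(vol, sigma=(sig_z, sig_xy, sig_xy))
            # renormalize so in-focus structures keep their nominal amplitude
            if vol.max() > 0:
                vol *= plane.max() / vol.max() if plane.max() > 0 else 1.0
        if name == "costain" and truth.mito_mask.any():
            truth.true_costain_mean_px = float(
                vol.max(axis=0)[truth.mito_mask].mean()
            )
        vol = vol + bg[None, :, :]
        if math.isfinite(cfg.photon_scale):
            vol = rng.poisson(np.clip(vol, 0, None) * cfg.photon_scale) / cfg.photon_scale
        if cfg.read_noise_sd > 0:
            vol = vol + rng.normal(0.0, cfg.read_noise_sd, size=vol.shape)
        channels.append(np.clip(np.rint(vol), 0, max_val))
    dtype = np.uint8 if cfg.bit_depth == 8 else np.uint16
    voxels = np.stack(channels).astype(dtype)
    stack = ImageStack(voxels=voxels, voxel_size_nm=cfg.voxel_size_nm, channel_names=names)
    geometry.true_overlap_fraction = truth.true_overlap_fraction
    return stack, truth


# ---------------------------------------------------------------------------
# cohorts


def generate_cohort(
    n_cells: int,
    spec_by_group: dict[str, NeuronSpec],
    cfg: RenderConfig,
    seed: int,
    out_dir: str | Path,
) -> pd.DataFrame:
    """Simulate ``n_cells`` per group and write a dataset directory.

    Per-cell seeds derive reproducibly from the master seed.  Each cell gets
    ``<group>_<i>/`` with ``stack.tif``, ``mito_table.csv``, ``tree.json``
    (image-frame µm), ``rois.json`` and ``meta.json``; a ``cells.csv``
    manifest indexes the dataset.  Re-running with the same arguments
    reproduces the dataset exactly.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1 per group")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(spec_by_group) * n_cells)
    records = []
    k = 0
    for group, spec in spec_by_group.items():
        for i in range(n_cells):
            cell_seed = int(children[k].generate_state(1)[0] % 2**31)
            k += 1
            cell_id = f"{group}_{i:03d}"
            cell_dir = out / cell_id
            if cell_dir.exists() and any(cell_dir.iterdir()):
                raise FileExistsError(f"output path collision: {cell_dir}")
            cell_dir.mkdir(parents=True, exist_ok=True)
            geom = generate_neuron(spec, cell_seed)
            cell_cfg = replace(cfg, seed=cell_seed + 1)
            stack, truth = render_stack(geom, cell_cfg)
            geom_img = truth.to_image_frame(geom)
            write_stack(cell_dir / "stack.tif", stack)
            geom_img.mito_table.to_csv(cell_dir / "mito_table.csv", index=False)
            write_tree_json(cell_dir / "tree.json", geom_img.tree)
            write_rois(
                cell_dir / "rois.json",
                [truth.soma_roi, truth.primary_roi, truth.arbor_roi] + truth.background_boxes,
            )
            meta = {
                "cell_id": cell_id,
                "group": group,
                "seed": cell_seed,
                "spec": _spec_to_json(spec),
                "render": _cfg_to_json(cell_cfg),
                "truth": {
                    "n_mito": int(len(geom.mito_table)),
                    "total_dendrite_length_um": geom.total_dendrite_length_um(),
                    "linear_density_per_um": geom.true_linear_density_per_um(),
                    "linear_occupancy_pct": geom.true_linear_occupancy_pct(),
                    "soma_fill_fraction": geom.true_soma_fill_fraction,
                    "soma_occupancy_pct": truth.true_soma_occupancy_pct,
                    "arbor_occupancy_pct": truth.true_arbor_occupancy_pct,
                    "overlap_fraction": truth.true_overlap_fraction,
                },
            }
            (cell_dir / "meta.json").write_text(json.dumps(meta, indent=1))
            records.append(
                {"cell_id": cell_id, "group": group, "seed": cell_seed, "path": str(cell_dir)}
            )
    manifest = pd.DataFrame(records)
    manifest.to_csv(out / "cells.csv", index=False)
    return manifest


def _spec_to_json(spec: NeuronSpec) -> dict:
    d = asdict(spec)
    d["mito_length_dist"] = [spec.mito_length_dist[0], spec.mito_length_dist[1]]
    return d


def _cfg_to_json(cfg: RenderConfig) -> dict:
    d = asdict(cfg)
    d["photon_scale"] = None if math.isinf(cfg.photon_scale) else cfg.photon_scale
    return d
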