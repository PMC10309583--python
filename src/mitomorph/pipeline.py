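"""End-to-end orchestration: per-cell analysis and cohort statistics.

A *cell directory* holds ``stack.tif`` (calibrated multi-channel stack),
``rois.json`` (soma / primary_dendrite / arbor polygons plus three
background boxes) and optionally ``tree.json`` (traced dendritic tree in
image-frame µm).  :func:`analyze_cell` runs projection → thresholding →
masks → the enabled metric families and returns one flat metrics row;
:func:`analyze_cohort` maps it over a dataset and compares every metric
between groups with the normality-driven test router.

The mitochondrial channel is thresholded on its raw maximum projection
(Moments algorithm) and the binary image cleaned outside each compartment
ROI; the enhancement chain is applied only to co-stain channels before
their occupancy/intensity quantification.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .coloc import manders, overlap_fraction
from .dendrite import (
    DendriteTree,
    assign_branch_orders,
    dendrite_summary,
    order_fractions,
    position_score,
    read_tree_json,
)
from .intensity import background_mean, ctcf, ctmf
from .io import RegionOfInterest, max_project, polygon_mask, read_rois, read_stack
from .morphometry import (
    SIZE_CLASSES,
    compartment_metrics,
    measure_length,
    segment_mitochondria,
)
from .network import mina_metrics
from .preprocess import PreprocessParams, binarize, moments_threshold, preprocess_chain
from .stats import compare_groups, significance_stars

__all__ = [
    "RunConfig",
    "ConfigurationError",
    "DataError",
    "analyze_cell",
    "analyze_cohort",
]

ANALYSES = (
    "soma",
    "primary_dendrite",
    "arbor",
    "network",
    "intensity",
    "coloc",
    "distribution",
)


class ConfigurationError(Exception):
    """Bad or incomplete run configuration (CLI exit code 2)."""


class DataError(Exception):
    """Missing or malformed input data (CLI exit code 3)."""


@dataclass
class RunConfig:
    """Resolved configuration of one analysis run."""

    channels: dict[str, str] = field(
        default_factory=lambda: {
            "cyto": "cyto",
            "mito": "mito",
            "costain": "costain",
            "lyso": "lyso",
        }
    )
    analyses: tuple[str, ...] = ("soma", "primary_dendrite", "arbor", "network", "distribution")
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    min_pixels: int = 4
    snap_um: float = 1.0
    order_interval: tuple[int, int] = (2, 5)
    z_range: tuple[int, int] | None = None
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.analyses) - set(ANALYSES)
        if unknown:
            raise ConfigurationError(f"unknown analyses: {sorted(unknown)}")


def _roi_by_label(rois: list[RegionOfInterest]) -> dict[str, RegionOfInterest]:
    return {r.label: r for r in rois if r.label != "background"}


def _require_rois(
    enabled: set[str], by_label: dict, n_background: int
) -> None:
    needed: dict[str, set[str]] = {
        "soma": {"soma"},
        "primary_dendrite": {"primary_dendrite"},
        "arbor": {"arbor"},
        "network": {"soma"},
        "intensity": {"soma"},
        "coloc": {"soma"},
        "distribution": {"arbor"},
    }
    missing = set()
    for a in enabled:
        missing |= needed.get(a, set()) - set(by_label)
    if "intensity" in enabled and n_background != 3:
        missing.add("background (x3)")
    if missing:
        raise ConfigurationError(
            f"missing ROI labels for enabled analyses: {sorted(missing)}"
        )


def analyze_cell(config: RunConfig, cell_dir: str | Path, cell_id: str | None = None) -> dict:
    """Run every enabled analysis on one cell directory.

    Returns ``{"metrics": {...}, "mito_table": DataFrame, "manifest": {...}}``.
    Raises :class:`ConfigurationError` for missing ROIs/channels and
    :class:`DataError` for missing files.
    """
    cell_dir = Path(cell_dir)
    if cell_id is None:
        cell_id = cell_dir.name
    stack_path = cell_dir / "stack.tif"
    roi_path = cell_dir / "rois.json"
    if not stack_path.exists() or not roi_path.exists():
        raise DataError(f"{cell_dir}: needs stack.tif and rois.json")
    stack = read_stack(stack_path)
    rois = read_rois(roi_path)
    by_label = _roi_by_label(rois)
    bg_boxes = [r for r in rois if r.label == "background"]
    enabled = set(config.analyses)
    _require_rois(enabled, by_label, len(bg_boxes))

    tree: DendriteTree | None = None
    if (cell_dir / "tree.json").exists():
        tree = assign_branch_orders(read_tree_json(cell_dir / "tree.json"))
    if ("arbor" in enabled or "distribution" in enabled) and tree is None:
        raise ConfigurationError(f"{cell_dir}: arbor/distribution analyses need tree.json")

    mito_name = config.channels["mito"]
    if mito_name not in stack.channel_names:
        raise ConfigurationError(
            f"mito channel {mito_name!r} not in stack channels {stack.channel_names}"
        )
    img_mito, px_nm = max_project(stack, mito_name, config.z_range)
    px_um = px_nm / 1000.0
    thr = moments_threshold(img_mito)

    metrics: dict[str, float] = {}
    mito_table = pd.DataFrame()

    if "soma" in enabled or "network" in enabled or "coloc" in enabled or "intensity" in enabled:
        soma_roi = by_label["soma"]
        soma_mask = polygon_mask(soma_roi, img_mito.shape)
        soma_bin = binarize(img_mito, soma_mask, threshold=thr)
        if "soma" in enabled:
            cm = compartment_metrics(
                soma_bin, soma_roi, [], px_nm, compartment="soma"
            )
            metrics["soma_occupancy_pct"] = cm.occupancy_pct
            metrics["soma_roi_area_um2"] = cm.roi_area_um2
            metrics["soma_mito_area_um2"] = cm.mito_area_um2
        if "network" in enabled:
            mm = mina_metrics(soma_bin, px_nm)
            metrics["mito_footprint_um2"] = mm.footprint_um2
            metrics["mean_branch_length_um"] = mm.mean_branch_length_um
            metrics["mean_summed_branch_length_um"] = mm.mean_summed_branch_length_um
            metrics["mean_network_branches"] = mm.mean_network_branches
        if "intensity" in enabled:
            co_name = config.channels.get("costain")
            if co_name not in stack.channel_names:
                raise ConfigurationError(f"costain channel {co_name!r} missing")
            img_co, _ = max_project(stack, co_name, config.z_range)
            bg = background_mean(img_co, bg_boxes, px_nm)
            enhanced = preprocess_chain(img_co, config.preprocess)
            co_mask = binarize(enhanced, soma_mask)
            metrics["costain_occupancy_pct"] = (
                100.0 * co_mask.sum() / max(soma_mask.sum(), 1)
            )
            metrics["costain_ctcf_soma"] = ctcf(img_co, soma_mask, bg, px_nm).ctcf
            if co_mask.any():
                metrics["costain_ctmf"] = ctmf(img_co, co_mask, bg, px_nm).ctmf
            metrics["background_mean"] = bg.background_mean
        if "coloc" in enabled:
            ly_name = config.channels.get("lyso")
            if ly_name not in stack.channel_names:
                raise ConfigurationError(f"lyso channel {ly_name!r} missing")
            img_ly, _ = max_project(stack, ly_name, config.z_range)
            ly_mask = binarize(img_ly, soma_mask)
            res = overlap_fraction(soma_bin, ly_mask, soma_roi, px_nm)
            metrics["overlap_pct_of_roi"] = res.overlap_pct_of_roi
            metrics["overlap_over_mito"] = (
                res.overlap_area_um2 / res.area_a_um2 if res.area_a_um2 > 0 else np.nan
            )
            try:
                m1, m2 = manders(img_mito, img_ly, soma_bin, ly_mask)
                metrics["manders_m1"], metrics["manders_m2"] = m1, m2
            except ZeroDivisionError:
                metrics["manders_m1"] = metrics["manders_m2"] = np.nan

    if "primary_dendrite" in enabled:
        pd_roi = by_label["primary_dendrite"]
        pd_mask = polygon_mask(pd_roi, img_mito.shape)
        pd_bin = binarize(img_mito, pd_mask, threshold=thr)
        cm = compartment_metrics(pd_bin, pd_roi, [], px_nm, compartment="primary_dendrite")
        metrics["primary_dendrite_occupancy_pct"] = cm.occupancy_pct

    if "arbor" in enabled or "distribution" in enabled:
        arbor_roi = by_label["arbor"]
        arbor_mask = polygon_mask(arbor_roi, img_mito.shape)
        arbor_bin = binarize(img_mito, arbor_mask, threshold=thr)
        objects = segment_mitochondria(arbor_bin, px_nm, min_pixels=config.min_pixels)
        for obj in objects:
            measure_length(obj, arbor_bin, px_nm)
        total_len, n_bp, _ = dendrite_summary(tree)
        if "arbor" in enabled:
            cm = compartment_metrics(
                arbor_bin, arbor_roi, objects, px_nm,
                dendrite_length_um=total_len, compartment="arbor",
            )
            metrics["dendritic_mito_count"] = float(cm.mito_count)
            metrics["arbor_occupancy_pct"] = cm.occupancy_pct
            metrics["linear_density_per_um"] = cm.linear_density_per_um
            metrics["linear_occupancy_pct"] = cm.linear_occupancy_pct
            metrics["area_per_length_um2_per_um"] = cm.area_per_length_um2_per_um
            metrics["total_dendrite_length_um"] = total_len
            metrics["n_branch_points"] = float(n_bp)
            lengths = np.array([o.length_um for o in objects])
            metrics["mean_mito_length_um"] = float(lengths.mean()) if len(lengths) else np.nan
            n = max(len(objects), 1)
            for cls in SIZE_CLASSES:
                metrics[f"pct_{cls}"] = (
                    100.0 * sum(o.size_class == cls for o in objects) / n
                )
        rows = []
        if "distribution" in enabled:
            assigned = []
            for obj in objects:
                cx, cy = obj.centroid_px
                a = position_score(
                    tree, (cx * px_um, cy * px_um), mito_id=obj.id, snap_um=config.snap_um
                )
                assigned.append(a)
            scores = [a.score for a in assigned if a.assigned]
            metrics["mean_position_score"] = float(np.mean(scores)) if scores else np.nan
            metrics["n_assigned"] = float(sum(a.assigned for a in assigned))
            metrics["n_unassigned"] = float(sum(not a.assigned for a in assigned))
            for order, pct in order_fractions(assigned, config.order_interval).items():
                metrics[f"order_{order}_pct"] = pct
            for obj, a in zip(objects, assigned):
                rows.append(
                    {
                        "cell_id": cell_id,
                        "mito_id": obj.id,
                        "length_um": obj.length_um,
                        "size_class": obj.size_class,
                        "branch_id": a.branch_id,
                        "order": a.order,
                        "score": a.score,
                        "cx_px": obj.centroid_px[0],
                        "cy_px": obj.centroid_px[1],
                    }
                )
        else:
            rows = [
                {
                    "cell_id": cell_id,
                    "mito_id": o.id,
                    "length_um": o.length_um,
                    "size_class": o.size_class,
                }
                for o in objects
            ]
        mito_table = pd.DataFrame(rows)

    manifest = {
        "cell_id": cell_id,
        "version": __version__,
        "threshold": float(thr),
        "config": {
            "channels": config.channels,
            "analyses": list(config.analyses),
            "preprocess": asdict(config.preprocess),
            "min_pixels": config.min_pixels,
            "snap_um": config.snap_um,
            "order_interval": list(config.order_interval),
            "z_range": list(config.z_range) if config.z_range else None,
            "seed": config.seed,
        },
    }
    return {"metrics": metrics, "mito_table": mito_table, "manifest": manifest}


def analyze_cohort(
    config: RunConfig,
    dataset_dir: str | Path,
    out_dir: str | Path | None = None,
) -> dict:
    """Analyze every cell of a dataset and compare metrics between groups.

    The dataset directory must contain ``cells.csv`` (cell_id, group, path)
    as written by :func:`mitomorph.synthetic.generate_cohort`.  Metrics with
    fewer than 3 cells in any group are skipped (with a note in the report).
    Returns per-cell metrics, the pooled mitochondrion table and the group
    comparison report; writes them as CSV when ``out_dir`` is given.
    """
    dataset_dir = Path(dataset_dir)
    manifest_path = dataset_dir / "cells.csv"
    if not manifest_path.exists():
        raise DataError(f"{dataset_dir}: missing cells.csv manifest")
    cells = pd.read_csv(manifest_path)
    per_cell = []
    mito_tables = []
    for rec in cells.itertuples():
        res = analyze_cell(config, rec.path, cell_id=rec.cell_id)
        row = {"cell_id": rec.cell_id, "group": rec.group}
        row.update(res["metrics"])
        per_cell.append(row)
        if len(res["mito_table"]):
            mito_tables.append(res["mito_table"].assign(group=rec.group))
    per_cell_df = pd.DataFrame(per_cell)
    mito_df = pd.concat(mito_tables, ignore_index=True) if mito_tables else pd.DataFrame()

    groups = sorted(per_cell_df["group"].unique())
    stats_rows = []
    if len(groups) >= 2:
        ga, gb = groups[:2]
        metric_cols = [
            c for c in per_cell_df.columns if c not in ("cell_id", "group")
        ]
        for col in metric_cols:
            x = per_cell_df.loc[per_cell_df.group == ga, col].dropna().to_numpy()
            y = per_cell_df.loc[per_cell_df.group == gb, col].dropna().to_numpy()
            if len(x) < 3 or len(y) < 3:
                stats_rows.append(
                    {"metric": col, "groups": f"{ga}|{gb}", "test": "skipped_n<3",
                     "statistic": np.nan, "p": np.nan, "stars": ""}
                )
                continue
            if np.ptp(np.concatenate([x, y])) == 0:
                stats_rows.append(
                    {"metric": col, "groups": f"{ga}|{gb}", "test": "skipped_constant",
                     "statistic": np.nan, "p": 1.0, "stars": "ns"}
                )
                continue
            res = compare_groups(x, y, alpha=config.alpha)
            stats_rows.append(
                {
                    "metric": col,
                    "groups": f"{ga}|{gb}",
                    "test": res.test_name,
                    "statistic": res.statistic,
                    "p": res.p_value,
                    "stars": significance_stars(res.p_value),
                    "trace": " ; ".join(res.decision_trace),
                }
            )
    stats_df = pd.DataFrame(stats_rows)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        per_cell_df.to_csv(out / "per_cell_metrics.csv", index=False)
        if len(mito_df):
            mito_df.to_csv(out / "mito_objects.csv", index=False)
        if len(stats_df):
            stats_df.to_csv(out / "group_stats.csv", index=False)
        (out / "run_manifest.json").write_text(
            json.dumps(
                {
                    "version": __version__,
                    "dataset": str(dataset_dir),
                    "n_cells": int(len(cells)),
                    "groups": groups,
                    "analyses": list(config.analyses),
                    "seed": config.seed,
                },
                indent=1,
            )
        )
    return {"per_cell": per_cell_df, "mito_table": mito_df, "group_stats": stats_df}
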