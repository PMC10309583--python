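"""Calibrated image stacks, 2D regions of interest and their file formats.

Every downstream quantification consumes a maximum z-projection of a single
channel together with hand-drawn (or synthetic) polygon/polyline ROIs.  This
module owns the conventions both rely on:

* voxels are indexed ``(channel, z, y, x)``; calibration is per-axis in nm;
* ROI vertices are ``(x, y)`` in continuous, 0-based pixel coordinates;
* polygon area uses the shoelace formula on the vertex path (the semantics of
  measuring a hand-drawn selection), while *masks* rasterize a polygon by
  including every pixel whose center lies inside it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import shapely
import tifffile
from shapely.geometry import Polygon

__all__ = [
    "ImageStack",
    "RegionOfInterest",
    "max_project",
    "roi_area_um2",
    "polygon_mask",
    "read_stack",
    "write_stack",
    "read_rois",
    "write_rois",
]

ROI_KINDS = ("polygon", "polyline", "box")


@dataclass
class ImageStack:
    """A calibrated multi-channel 3D fluorescence stack.

    Parameters
    ----------
    voxels
        Intensity array indexed ``(channel, z, y, x)``; non-negative.
    voxel_size_nm
        Physical voxel extent ``(x, y, z)`` in nanometres.
    channel_names
        One label per channel, e.g. ``["cyto", "mito"]``.
    """

    voxels: np.ndarray
    voxel_size_nm: tuple[float, float, float]
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 4:
            raise ValueError(
                f"voxels must be (channel, z, y, x), got ndim={self.voxels.ndim}"
            )
        if any(v <= 0 for v in self.voxel_size_nm):
            raise ValueError(f"voxel_size_nm must be positive, got {self.voxel_size_nm}")
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(self.voxels.shape[0])]
        if len(self.channel_names) != self.voxels.shape[0]:
            raise ValueError("channel_names length must match channel axis")
        if np.nanmin(self.voxels) < 0:
            raise ValueError("intensities must be non-negative")

    @property
    def pixel_size_nm(self) -> float:
        """Lateral pixel size (x); x and y calibration are assumed equal."""
        return float(self.voxel_size_nm[0])

    def channel_index(self, channel: int | str) -> int:
        if isinstance(channel, (int, np.integer)):
            if not 0 <= channel < self.voxels.shape[0]:
                raise KeyError(f"channel index {channel} out of range")
            return int(channel)
        try:
            return self.channel_names.index(channel)
        except ValueError:
            raise KeyError(
                f"unknown channel {channel!r}; have {self.channel_names}"
            ) from None


@dataclass
class RegionOfInterest:
    """A 2D polygon, polyline or box in pixel coordinates.

    ``vertices`` is an ``(n, 2)`` array of ``(x, y)`` points.  Polygons must be
    simple (non self-intersecting) with at least 3 vertices; polylines need at
    least 2.  ``label`` names the role the ROI plays in the analysis (``soma``,
    ``primary_dendrite``, ``arbor``, ``background``, ``mito_trace``,
    ``spine_segment``...).
    """

    kind: str
    vertices: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ROI_KINDS:
            raise ValueError(f"kind must be one of {ROI_KINDS}, got {self.kind!r}")
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise ValueError("vertices must be an (n, 2) array of (x, y)")
        n = len(self.vertices)
        if self.kind in ("polygon", "box"):
            if n < 3:
                raise ValueError("polygon needs >= 3 vertices")
            if not Polygon(self.vertices).is_simple:
                raise ValueError("polygon must be simple (non self-intersecting)")
        elif n < 2:
            raise ValueError("polyline needs >= 2 vertices")

    def to_polygon(self) -> Polygon:
        if self.kind == "polyline":
            raise ValueError(f"ROI {self.label!r} is a polyline, not an area")
        return Polygon(self.vertices)


def max_project(
    stack: ImageStack,
    channel: int | str,
    z_range: tuple[int, int] | None = None,
) -> tuple[np.ndarray, float]:
    """Maximum z-projection of one channel.

    Parameters
    ----------
    stack, channel
        Stack and channel label/index to project.
    z_range
        Optional half-open slice ``(z0, z1)`` of optical sections to include
        (the sections containing the structure of interest); default all.

    Returns
    -------
    (image, pixel_size_nm)
        2D ``(y, x)`` per-pixel maximum and the lateral calibration.
    """
    ci = stack.channel_index(channel)
    nz = stack.voxels.shape[1]
    if z_range is None:
        z0, z1 = 0, nz
    else:
        z0, z1 = z_range
        if not (0 <= z0 < z1 <= nz):
            raise ValueError(f"z_range {z_range} outside stack of {nz} sections")
    return stack.voxels[ci, z0:z1].max(axis=0), stack.pixel_size_nm


def roi_area_um2(roi: RegionOfInterest, pixel_size_nm: float) -> float:
    """Polygon area in µm², shoelace formula × pixel-area calibration."""
    poly = roi.to_polygon()  # raises on polylines
    px_um = pixel_size_nm / 1000.0
    return float(poly.area) * px_um * px_um


def polygon_mask(roi: RegionOfInterest, shape: tuple[int, int]) -> np.ndarray:
    """Boolean ``(y, x)`` mask of pixels whose centers fall inside the polygon."""
    poly = roi.to_polygon()
    h, w = shape
    # Pixel (iy, ix) has its center at continuous coordinates (ix, iy).
    xs, ys = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
    shapely.prepare(poly)
    inside = shapely.contains_xy(poly, xs.ravel(), ys.ravel())
    return inside.reshape(h, w)


# ---------------------------------------------------------------------------
# file formats: multi-page TIFF with JSON calibration, ROI JSON


def write_stack(path: str | Path, stack: ImageStack) -> None:
    """Write a stack as multi-page TIFF; calibration goes in shaped metadata."""
    tifffile.imwrite(
        str(path),
        stack.voxels,
        photometric="minisblack",
        metadata={
            "axes": "CZYX",
            "voxel_size_nm": list(stack.voxel_size_nm),
            "channel_names": list(stack.channel_names),
        },
    )


def read_stack(path: str | Path) -> ImageStack:
    with tifffile.TiffFile(str(path)) as tif:
        voxels = tif.asarray()
        meta = (tif.shaped_metadata or [{}])[0]
    if voxels.ndim == 3:  # single channel written without C axis
        voxels = voxels[None]
    vs = meta.get("voxel_size_nm")
    if vs is None:
        raise ValueError(f"{path}: missing voxel_size_nm metadata")
    return ImageStack(
        voxels=voxels,
        voxel_size_nm=tuple(float(v) for v in vs),
        channel_names=list(meta.get("channel_names", [])),
    )


def write_rois(path: str | Path, rois: list[RegionOfInterest]) -> None:
    payload = [
        {"kind": r.kind, "label": r.label, "vertices": r.vertices.tolist()}
        for r in rois
    ]
    Path(path).write_text(json.dumps(payload, indent=1))


def read_rois(path: str | Path) -> list[RegionOfInterest]:
    payload = json.loads(Path(path).read_text())
    return [
        RegionOfInterest(kind=d["kind"], vertices=np.asarray(d["vertices"]), label=d.get("label", ""))
        for d in payload
    ]
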