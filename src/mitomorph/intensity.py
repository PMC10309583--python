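"""Background-corrected fluorescence intensity: CTCF and CTMF.

Corrected total cell fluorescence (CTCF) subtracts the expected background
contribution from the integrated intensity of an ROI::

    CTCF = integrated density − (ROI size × mean background fluorescence)

with the ROI size expressed in pixels and the background mean estimated from
three small (5×5 µm) boxes placed over signal-free regions.  CTMF is the same
corrected quantity computed with the thresholded mitochondrial mask as the
ROI, normalized to the mask's area in µm² — intensity per unit mitochondrial
area.  Negative corrected values are reported as-is (and flagged), never
clipped, so that the statistics downstream stay linear.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import RegionOfInterest, polygon_mask

__all__ = ["BackgroundEstimate", "IntensityResult", "background_mean", "ctcf", "ctmf"]

_BOX_SIDE_UM = 5.0


@dataclass
class BackgroundEstimate:
    box_means: tuple[float, float, float]
    background_mean: float


@dataclass
class IntensityResult:
    integrated_density: float
    roi_pixels: int
    roi_area_um2: float
    ctcf: float
    ctmf: float | None = None
    negative_flag: bool = False


def _roi_to_mask(roi: RegionOfInterest | np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    if isinstance(roi, RegionOfInterest):
        return polygon_mask(roi, shape)
    mask = np.asarray(roi, dtype=bool)
    if mask.shape != shape:
        raise ValueError("mask shape does not match image")
    return mask


def background_mean(
    image: np.ndarray,
    boxes: list[RegionOfInterest],
    pixel_size_nm: float,
    box_tolerance_px: float = 1.0,
) -> BackgroundEstimate:
    """Average the mean intensity of three 5×5 µm background boxes.

    Each box must be (within ``box_tolerance_px`` pixels) 5 µm on a side and
    lie fully inside the image.
    """
    image = np.asarray(image, dtype=float)
    if len(boxes) != 3:
        raise ValueError(f"exactly three background boxes required, got {len(boxes)}")
    px_um = pixel_size_nm / 1000.0
    side_px = _BOX_SIDE_UM / px_um
    means = []
    for box in boxes:
        v = box.vertices
        w = v[:, 0].max() - v[:, 0].min()
        h = v[:, 1].max() - v[:, 1].min()
        if abs(w - side_px) > box_tolerance_px or abs(h - side_px) > box_tolerance_px:
            raise ValueError(
                f"background box {box.label!r} is {w:.1f}x{h:.1f} px, "
                f"expected {side_px:.1f} px (5x5 um)"
            )
        if v.min() < -0.5 or v[:, 0].max() > image.shape[1] - 0.5 or v[:, 1].max() > image.shape[0] - 0.5:
            raise ValueError(f"background box {box.label!r} lies outside the image")
        mask = polygon_mask(box, image.shape)
        means.append(float(image[mask].mean()))
    return BackgroundEstimate(
        box_means=tuple(means), background_mean=float(np.mean(means))
    )


def ctcf(
    image: np.ndarray,
    roi: RegionOfInterest | np.ndarray,
    bg: BackgroundEstimate,
    pixel_size_nm: float | None = None,
) -> IntensityResult:
    """Corrected total cell fluorescence over an ROI (polygon or mask)."""
    image = np.asarray(image, dtype=float)
    mask = _roi_to_mask(roi, image.shape)
    n = int(mask.sum())
    if n == 0:
        raise ValueError("ROI mask is empty")
    integrated = float(image[mask].sum())
    value = integrated - n * bg.background_mean
    area = n * (pixel_size_nm / 1000.0) ** 2 if pixel_size_nm else float("nan")
    return IntensityResult(
        integrated_density=integrated,
        roi_pixels=n,
        roi_area_um2=area,
        ctcf=value,
        negative_flag=value < 0,
    )


def ctmf(
    image: np.ndarray,
    mito_mask: np.ndarray,
    bg: BackgroundEstimate,
    pixel_size_nm: float,
) -> IntensityResult:
    """Corrected total mitochondrial fluorescence per µm² of mitochondrial area.

    CTCF with the mitochondrial mask as the ROI, divided by the mask area in
    µm².  The numerator is background-corrected, so a uniformly stained mask
    of any size yields the same CTMF.
    """
    res = ctcf(image, mito_mask, bg, pixel_size_nm=pixel_size_nm)
    res.ctmf = res.ctcf / res.roi_area_um2
    return res
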