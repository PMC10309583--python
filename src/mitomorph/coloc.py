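"""Lysosome/mitochondria-style colocalization: overlap area and Manders' M1/M2.

"Presence" of a channel is defined by its binary mask (thresholded upstream
with the same Moments policy as every other mask in the package), never by a
threshold internal to these functions.  The overlap is the pixelwise AND of
the two masks; Manders' coefficients weight the overlap by intensity::

    M1 = Σ_{B present} I_A / Σ_{A present} I_A
    M2 = Σ_{A present} I_B / Σ_{B present} I_B

so that M1 is the fraction of channel A's integrated intensity residing
where channel B is present, and symmetrically for M2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import RegionOfInterest, roi_area_um2

__all__ = ["ColocResult", "overlap_fraction", "manders"]


@dataclass
class ColocResult:
    overlap_area_um2: float
    overlap_pct_of_roi: float
    area_a_um2: float
    area_b_um2: float
    m1: float | None = None
    m2: float | None = None


def overlap_fraction(
    mask_a: np.ndarray,
    mask_b: np.ndarray,
    roi: RegionOfInterest,
    pixel_size_nm: float,
) -> ColocResult:
    """Area of A∧B and its percentage of the ROI area (masks cleaned to ROI)."""
    mask_a = np.asarray(mask_a, dtype=bool)
    mask_b = np.asarray(mask_b, dtype=bool)
    if mask_a.shape != mask_b.shape:
        raise ValueError(f"mask shapes differ: {mask_a.shape} vs {mask_b.shape}")
    px2 = (pixel_size_nm / 1000.0) ** 2
    overlap = mask_a & mask_b
    roi_area = roi_area_um2(roi, pixel_size_nm)
    return ColocResult(
        overlap_area_um2=float(overlap.sum()) * px2,
        overlap_pct_of_roi=100.0 * float(overlap.sum()) * px2 / roi_area,
        area_a_um2=float(mask_a.sum()) * px2,
        area_b_um2=float(mask_b.sum()) * px2,
    )


def manders(
    image_a: np.ndarray,
    image_b: np.ndarray,
    mask_a: np.ndarray,
    mask_b: np.ndarray,
) -> tuple[float, float]:
    """Manders' colocalization coefficients (M1, M2).

    M1: fraction of channel A's masked intensity that falls where B is
    present; M2 symmetrically for channel B.  Raises if either channel has
    zero integrated intensity over its own mask.
    """
    image_a = np.asarray(image_a, dtype=float)
    image_b = np.asarray(image_b, dtype=float)
    mask_a = np.asarray(mask_a, dtype=bool)
    mask_b = np.asarray(mask_b, dtype=bool)
    if not (image_a.shape == image_b.shape == mask_a.shape == mask_b.shape):
        raise ValueError("images and masks must share one shape")
    denom_a = float(image_a[mask_a].sum())
    denom_b = float(image_b[mask_b].sum())
    if denom_a == 0 or denom_b == 0:
        raise ZeroDivisionError("undefined Manders coefficient: zero total intensity")
    m1 = float(image_a[mask_b].sum()) / denom_a
    m2 = float(image_b[mask_a].sum()) / denom_b
    return m1, m2
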