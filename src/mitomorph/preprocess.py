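"""Contrast-enhancement chain and moment-preserving auto-threshold.

The mitochondrial channel is turned into a binary mask in two stages:

1. an optional four-step enhancement chain — unsharp mask, rolling-ball
   background subtraction, CLAHE, median filter — used before quantifying
   co-stain channels (MFN2/OPA1/OxPhos-style immunostains);
2. Tsai's moment-preserving ("Moments") threshold on the gray-level
   histogram, shared by every binarization in the package.

All operations are deterministic and assume an 8-bit working range
(images are clipped to [0, 255] between steps).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import exposure, morphology, restoration

__all__ = [
    "PreprocessParams",
    "preprocess_chain",
    "moments_threshold",
    "moments_threshold_hist",
    "binarize",
]

_MAX_8BIT = 255.0


@dataclass(frozen=True)
class PreprocessParams:
    """Parameters of the four-step enhancement chain.

    Defaults follow the standard confocal immunostain workflow: unsharp mask
    (radius 2 px, weight 0.4), rolling-ball background subtraction (radius
    50 px), CLAHE (block 9 px, 256 bins, max slope 4), median filter
    (radius 1 px).  A step can be disabled at its identity limit:
    ``unsharp_weight=0``, ``rolling_ball_radius=None``, ``clahe_max_slope<=1``,
    ``median_radius=0``.
    """

    unsharp_radius: float = 2.0
    unsharp_weight: float = 0.4
    rolling_ball_radius: float | None = 50.0
    clahe_block: int = 9
    clahe_bins: int = 256
    clahe_max_slope: float = 4.0
    median_radius: int = 1

    def __post_init__(self) -> None:
        if self.unsharp_radius <= 0:
            raise ValueError("unsharp_radius must be > 0")
        if not 0.0 <= self.unsharp_weight < 1.0:
            raise ValueError("unsharp_weight must be in [0, 1)")
        if self.rolling_ball_radius is not None and self.rolling_ball_radius <= 0:
            raise ValueError("rolling_ball_radius must be > 0 or None")
        if self.clahe_block <= 0:
            raise ValueError("clahe_block must be > 0")
        if self.clahe_bins < 2:
            raise ValueError("clahe_bins must be >= 2")
        if self.median_radius < 0:
            raise ValueError("median_radius must be >= 0")


def _as_2d_float(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError(f"expected a 2D single-channel image, got ndim={image.ndim}")
    return image.astype(float, copy=True)


def preprocess_chain(image: np.ndarray, params: PreprocessParams | None = None) -> np.ndarray:
    """Apply unsharp mask → background subtraction → CLAHE → median filter.

    The unsharp mask uses the classical mask-weight formula
    ``(img − w·G_σ(img)) / (1 − w)`` with ``σ = unsharp_radius``.  Rolling-ball
    background subtraction removes slowly varying background by subtracting a
    grayscale ball-opening of the image.  CLAHE is tile-based adaptive
    histogram equalization whose clip limit is ``max_slope / bins`` (slope 1 =
    no equalization).  Output is float, clipped to the 8-bit range.
    """
    if params is None:
        params = PreprocessParams()
    img = np.clip(_as_2d_float(image), 0.0, _MAX_8BIT)

    if params.unsharp_weight > 0.0:
        blurred = ndimage.gaussian_filter(img, sigma=params.unsharp_radius)
        img = (img - params.unsharp_weight * blurred) / (1.0 - params.unsharp_weight)
        img = np.clip(img, 0.0, _MAX_8BIT)

    if params.rolling_ball_radius is not None and math.isfinite(params.rolling_ball_radius):
        background = restoration.rolling_ball(img, radius=params.rolling_ball_radius)
        img = np.clip(img - background, 0.0, _MAX_8BIT)

    if params.clahe_max_slope > 1.0:
        clip = min(1.0, params.clahe_max_slope / params.clahe_bins)
        eq = exposure.equalize_adapthist(
            img / _MAX_8BIT,
            kernel_size=params.clahe_block,
            clip_limit=clip,
            nbins=params.clahe_bins,
        )
        img = np.clip(eq * _MAX_8BIT, 0.0, _MAX_8BIT)

    if params.median_radius > 0:
        img = ndimage.median_filter(
            img, footprint=morphology.disk(params.median_radius)
        )

    return img


def _histogram_256(image: np.ndarray) -> np.ndarray:
    """Integer histogram over gray levels 0..255 (values rounded and clipped)."""
    levels = np.clip(np.rint(np.asarray(image, dtype=float)), 0, 255).astype(np.intp)
    return np.bincount(levels.ravel(), minlength=256).astype(float)


def moments_threshold_hist(hist: np.ndarray) -> int:
    """Tsai's moment-preserving threshold of a 256-bin gray-level histogram.

    Finds the bilevel image that preserves the first three gray-level moments
    of the input.  The preserved-moment system yields two representative
    levels ``z0 < z1`` and the fraction ``p0`` of pixels that should map to
    the lower level; the threshold is the gray level whose cumulative
    histogram fraction is closest to ``p0``.  Pixels strictly above the
    returned level are foreground.
    """
    hist = np.asarray(hist, dtype=float)
    if hist.shape != (256,):
        raise ValueError("expected a 256-bin histogram")
    total = hist.sum()
    if total <= 0 or np.count_nonzero(hist) < 2:
        raise ValueError("degenerate histogram: need >= 2 distinct gray levels")
    p = hist / total
    z = np.arange(256, dtype=float)
    m1 = float(np.sum(p * z))
    m2 = float(np.sum(p * z**2))
    m3 = float(np.sum(p * z**3))
    cd = m2 - m1 * m1  # variance; > 0 for non-degenerate histograms
    c0 = (-m2 * m2 + m1 * m3) / cd
    c1 = (-m3 + m2 * m1) / cd
    disc = max(c1 * c1 - 4.0 * c0, 0.0)
    z0 = 0.5 * (-c1 - math.sqrt(disc))
    z1 = 0.5 * (-c1 + math.sqrt(disc))
    if z1 == z0:
        raise ValueError("degenerate moment system")
    p0 = (z1 - m1) / (z1 - z0)  # target fraction of pixels at/below the cut
    cum = np.cumsum(p)
    return int(np.argmin(np.abs(cum - p0)))


def moments_threshold(image: np.ndarray) -> int:
    """Moment-preserving threshold of an 8-bit-range 2D image (see hist form)."""
    img = _as_2d_float(image)
    return moments_threshold_hist(_histogram_256(img))


def binarize(
    image: np.ndarray,
    roi_mask: np.ndarray | None = None,
    threshold: float | None = None,
) -> np.ndarray:
    """Threshold an image (strictly greater-than) and clean outside the ROI.

    ``threshold`` defaults to the Moments threshold computed on the pixels
    inside ``roi_mask`` (or the whole image if no ROI is given).
    """
    img = _as_2d_float(image)
    if threshold is None:
        if roi_mask is not None:
            vals = img[np.asarray(roi_mask, dtype=bool)]
            threshold = moments_threshold_hist(_histogram_256(vals))
        else:
            threshold = moments_threshold(img)
    fg = img > threshold
    if roi_mask is not None:
        fg &= np.asarray(roi_mask, dtype=bool)
    return fg
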