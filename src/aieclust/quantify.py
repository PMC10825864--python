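"""ROI segmentation and intensity quantification.

Reproduces the analysis chain applied to each widefield image: an
edge-detection segmentation defines the cell area (the region of interest),
the mean fluorescent intensity is the sum of masked pixel values divided by
the masked area, and a signal-to-noise ratio contrasts the cell signal with
the background outside the (dilated) ROI.

Segmentation pipeline (every stage configurable):

    Gaussian smoothing (smooth_sigma)
      -> Sobel gradient magnitude
      -> threshold (Otsu on the gradient map, or a fixed value)
      -> morphological closing (disk, closing_radius)
      -> hole filling
      -> removal of connected components smaller than min_object_area

The Sobel kernels are the standard 3x3 pair
    [[1, 0, -1], [2, 0, -2], [1, 0, -1]] / 4   (and its transpose),
combined as the Euclidean gradient magnitude.

The SNR definition (the original formula being unavailable) is

    SNR = (mean_foreground - mean_background) / sd_background

with foreground = masked pixels and background = the complement of the ROI
dilated by ``bg_exclusion_radius`` pixels (to keep the PSF halo out of the
background estimate). The sd is the population standard deviation (ddof=0).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import filters, morphology

from .aie_optics import MicroImage

__all__ = [
    "SegmentationParams",
    "ROIMask",
    "QuantResult",
    "segment_cells",
    "mean_masked_intensity",
    "compute_snr",
]


@dataclass
class SegmentationParams:
    smooth_sigma: float = 0.8
    gradient_threshold_method: str = "otsu"  # "otsu" | "fixed"
    fixed_threshold: float | None = None
    closing_radius: int = 3
    min_object_area: int = 50

    def __post_init__(self):
        if self.smooth_sigma < 0 or self.closing_radius < 0 or self.min_object_area < 0:
            raise ValueError("smooth_sigma, closing_radius, min_object_area must be >= 0")
        if self.gradient_threshold_method not in ("otsu", "fixed"):
            raise ValueError("gradient_threshold_method must be 'otsu' or 'fixed'")
        if self.gradient_threshold_method == "fixed" and self.fixed_threshold is None:
            raise ValueError("fixed method requires fixed_threshold")


@dataclass
class ROIMask:
    """Boolean pixel mask of the segmented cell area."""

    mask: np.ndarray

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2D")

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())


@dataclass
class QuantResult:
    sum_intensity: float
    area_px: int
    mean_intensity: float
    snr: float | None = None


def segment_cells(image: MicroImage, params: SegmentationParams | None = None) -> ROIMask:
    """Segment the cell area of a widefield image by edge detection."""
    params = params or SegmentationParams()
    px = np.asarray(image.pixels, dtype=float)
    if px.size == 0:
        raise ValueError("image is empty")
    smoothed = ndi.gaussian_filter(px, params.smooth_sigma) if params.smooth_sigma > 0 else px
    grad = filters.sobel(smoothed)
    if params.gradient_threshold_method == "otsu":
        if np.ptp(grad) == 0:
            warnings.warn("gradient map is constant (no edges); returning an empty mask")
            return ROIMask(mask=np.zeros_like(px, dtype=bool))
        thr = filters.threshold_otsu(grad)
    else:
        thr = params.fixed_threshold
    mask = grad > thr
    if params.closing_radius > 0:
        mask = ndi.binary_closing(mask, structure=morphology.disk(params.closing_radius))
    mask = ndi.binary_fill_holes(mask)
    if params.min_object_area > 0:
        # drop connected components with fewer than min_object_area pixels
        labels, n = ndi.label(mask)
        if n:
            sizes = np.bincount(labels.ravel())
            small = sizes < params.min_object_area
            small[0] = False
            mask &= ~small[labels]
    return ROIMask(mask=mask)


def _check_shapes(image: MicroImage, roi: ROIMask) -> None:
    if image.pixels.shape != roi.mask.shape:
        raise ValueError(
            f"image shape {image.pixels.shape} does not match mask shape {roi.mask.shape}"
        )


def mean_masked_intensity(image: MicroImage, roi: ROIMask) -> QuantResult:
    """Sum of masked pixel values divided by the masked area (photons/px)."""
    _check_shapes(image, roi)
    area = roi.area_px
    if area == 0:
        raise ValueError("mean intensity is undefined for an empty mask")
    total = float(image.pixels[roi.mask].sum())
    return QuantResult(sum_intensity=total, area_px=area, mean_intensity=total / area)


def compute_snr(image: MicroImage, roi: ROIMask, bg_exclusion_radius: int = 5) -> float:
    """Background-subtracted mean over background sd (see module docstring)."""
    _check_shapes(image, roi)
    if roi.area_px == 0:
        raise ValueError("SNR is undefined for an empty mask")
    if bg_exclusion_radius > 0:
        dilated = ndi.binary_dilation(roi.mask, structure=morphology.disk(bg_exclusion_radius))
    else:
        dilated = roi.mask
    bg = ~dilated
    if not bg.any():
        raise ValueError("background region is empty")
    fg_vals = image.pixels[roi.mask]
    bg_vals = image.pixels[bg]
    sd_bg = float(bg_vals.std(ddof=0))
    if sd_bg == 0:
        raise ValueError("background sd is zero; SNR undefined")
    return float((fg_vals.mean() - bg_vals.mean()) / sd_bg)
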