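"""Two-channel colocalization statistics.

Pixel-wise Pearson correlation between two fluorescence channels inside the
segmented cell area — the standard colocalization measure for co-staining
experiments — plus the joint 2D intensity histogram used to visualise the
pixel-intensity relationship between channels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .aie_optics import MicroImage
from .quantify import ROIMask

__all__ = ["ColocResult", "pearson_coloc", "intensity_histogram_2d"]


@dataclass
class ColocResult:
    pcc: float | None
    n_pixels: int
    hist2d: np.ndarray | None = None
    edges_a: np.ndarray | None = None
    edges_b: np.ndarray | None = None


def _masked_pair(channel_a: MicroImage, channel_b: MicroImage, mask: ROIMask | None):
    a = np.asarray(channel_a.pixels, dtype=float)
    b = np.asarray(channel_b.pixels, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"channel shapes differ: {a.shape} vs {b.shape}")
    if mask is None:
        m = np.ones(a.shape, dtype=bool)
    else:
        if mask.mask.shape != a.shape:
            raise ValueError("mask shape does not match channels")
        m = mask.mask
    return a[m], b[m]


def pearson_coloc(
    channel_a: MicroImage, channel_b: MicroImage, mask: ROIMask | None = None
) -> float:
    """Pearson correlation cov(A,B)/(sd(A) sd(B)) over masked pixel pairs.

    With mask=None the whole frame is used; the default analysis masks to
    the segmented cell area, since only cellular photons carry the
    colocalization signal.
    """
    a, b = _masked_pair(channel_a, channel_b, mask)
    if a.size < 2:
        raise ValueError("PCC needs at least 2 masked pixels")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("PCC is undefined for a constant channel within the mask")
    return float(np.corrcoef(a, b)[0, 1])


def intensity_histogram_2d(
    channel_a: MicroImage,
    channel_b: MicroImage,
    mask: ROIMask | None = None,
    bins: int = 64,
) -> ColocResult:
    """Joint intensity histogram over equal-width bins spanning each
    channel's masked min–max range (half-open bins, last bin closed)."""
    if bins < 2:
        raise ValueError("bins must be >= 2")
    a, b = _masked_pair(channel_a, channel_b, mask)
    if a.size == 0:
        raise ValueError("mask is empty")
    hist, ea, eb = np.histogram2d(a, b, bins=bins)
    return ColocResult(pcc=None, n_pixels=int(a.size), hist2d=hist, edges_a=ea, edges_b=eb)
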