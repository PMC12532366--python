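"""Plaque quantification from single-channel fluorescence images.

The workflow mirrors standard confocal plaque analysis: median-filter
denoising, threshold segmentation (between-class-variance maximization
by default), morphological cleanup (hole filling, then opening and
closing with a disk), connected-component counting with a minimum-area
filter, and the plaque burden as percentage of image area.  Burden is
then correlated (Pearson) against mean entanglement metrics per region.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.stats import pearsonr
from skimage.morphology import closing, disk, opening

__all__ = [
    "PlaqueQuant",
    "denoise",
    "otsu_threshold",
    "segment",
    "refine",
    "quantify",
    "analyze_image",
    "correlate_burden",
]


@dataclass
class PlaqueQuant:
    """Quantification of one image: count, burden and per-plaque areas."""

    count: int
    area_percent: float
    areas: np.ndarray
    mask: np.ndarray


def denoise(image: np.ndarray, kernel_radius: int = 2) -> np.ndarray:
    """Median filter with a square (2r+1)² window; edges by reflection."""
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("expected a 2D single-channel image")
    if kernel_radius < 1:
        raise ValueError("kernel_radius must be >= 1")
    return ndimage.median_filter(image, size=2 * kernel_radius + 1, mode="reflect")


def otsu_threshold(image: np.ndarray) -> float:
    """Threshold maximizing the between-class variance (Otsu criterion).

    Computed exactly over the sorted sample values rather than a binned
    histogram, which makes the resulting mask invariant under any
    positive affine rescaling of the intensities.  Returns the smallest
    value of the upper class; segment with ``image >= threshold``.
    """
    vals = np.sort(np.asarray(image, dtype=float).ravel())
    n = vals.size
    if vals[0] == vals[-1]:
        raise ValueError("cannot auto-threshold a constant image")
    csum = np.cumsum(vals)
    total = csum[-1]
    # split after index k (lower class vals[:k+1]); candidates between
    # distinct neighbors only
    k = np.arange(1, n)
    valid = vals[1:] > vals[:-1]
    w0 = k / n
    w1 = 1.0 - w0
    mu0 = csum[:-1] / k
    mu1 = (total - csum[:-1]) / (n - k)
    bcv = np.where(valid, w0 * w1 * (mu0 - mu1) ** 2, -np.inf)
    split = int(np.argmax(bcv))
    return float(vals[split + 1])


def segment(image: np.ndarray, threshold: float | None = None) -> np.ndarray:
    """Binary mask of pixels >= threshold (auto Otsu when not given).

    A constant image with automatic thresholding yields an empty mask
    with a warning rather than an error.
    """
    image = np.asarray(image, dtype=float)
    if threshold is None:
        if np.ptp(image) == 0:
            warnings.warn("constant image: auto-threshold yields an empty mask")
            return np.zeros(image.shape, dtype=bool)
        threshold = otsu_threshold(image)
    return image >= threshold


def refine(mask: np.ndarray, se_radius: int = 2) -> np.ndarray:
    """Fill interior holes, then smooth by opening followed by closing.

    The structuring element is a disk of the given radius; background
    components not touching the border are treated as holes.
    """
    mask = np.asarray(mask, dtype=bool)
    filled = ndimage.binary_fill_holes(mask)
    if se_radius < 1:
        return filled
    se = disk(se_radius)
    return closing(opening(filled, se), se).astype(bool)


def quantify(mask: np.ndarray, min_area: int = 10) -> PlaqueQuant:
    """Count 8-connected components and compute the plaque-area percentage.

    Components smaller than ``min_area`` pixels are dropped (speckle
    suppression) before both the count and the area computation.
    """
    mask = np.asarray(mask, dtype=bool)
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return PlaqueQuant(0, 0.0, np.array([], dtype=int), mask.copy())
    areas = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1)).astype(int)
    keep = areas >= min_area
    kept_ids = np.flatnonzero(keep) + 1
    final = np.isin(labels, kept_ids)
    kept_areas = areas[keep]
    return PlaqueQuant(
        count=int(keep.sum()),
        area_percent=100.0 * final.sum() / mask.size,
        areas=kept_areas,
        mask=final,
    )


def analyze_image(
    image: np.ndarray,
    median_radius: int = 2,
    threshold: float | None = None,
    se_radius: int = 2,
    min_area: int = 10,
) -> PlaqueQuant:
    """Full quantification pipeline: denoise -> segment -> refine -> quantify."""
    return quantify(
        refine(segment(denoise(image, median_radius), threshold), se_radius),
        min_area,
    )


def correlate_burden(area_percents, metric_means) -> dict[str, float]:
    """Pearson correlation and least-squares trendline of burden vs metric.

    Returns ``{"r", "p_value", "slope", "intercept"}`` for plaque-area
    percentage against a mean entanglement metric across regions.
    """
    x = np.asarray(area_percents, dtype=float)
    y = np.asarray(metric_means, dtype=float)
    if x.size != y.size:
        raise ValueError("paired inputs must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in one of the variables")
    r, p = pearsonr(x, y)
    slope, intercept = np.polyfit(x, y, 1)
    return {
        "r": float(r),
        "p_value": float(p),
        "slope": float(slope),
        "intercept": float(intercept),
    }
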