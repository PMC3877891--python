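"""2-D image quantification operators.

Seeded-watershed membrane masking, background-corrected membrane intensity,
a fixed-order bright-spot counting pipeline, pixelwise colocalization and
dye-positivity fractions.

Conventions: pixel coordinates are 0-based ``(row, col)``; masks and label
maps share this convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import filters, measure, morphology, segmentation

__all__ = [
    "MembraneMask",
    "SpotParams",
    "seeded_watershed",
    "membrane_mean_intensity",
    "count_bright_spots",
    "coloc_pearson",
    "pi_positive_fraction",
]


@dataclass
class MembraneMask:
    """Watershed labels plus the ridge-of-boundary membrane mask."""

    label_map: np.ndarray
    mask: np.ndarray
    ridge_width: int


@dataclass(frozen=True)
class SpotParams:
    """Parameters of the spot-counting pipeline.

    ``gauss_sigma`` smooths shot noise, ``tophat_radius`` (disk structuring
    element) removes objects larger than the spots of interest, ``h_maxima``
    is the extended-maxima depth on the max-normalized image (0-1 scale).
    """

    gauss_sigma: float = 1.5
    tophat_radius: int = 6
    h_maxima: float = 0.1

    def __post_init__(self):
        if self.gauss_sigma <= 0 or self.tophat_radius <= 0 or self.h_maxima <= 0:
            raise ValueError("all spot parameters must be positive")
        if self.tophat_radius <= self.gauss_sigma:
            raise ValueError("tophat_radius must exceed gauss_sigma")


def seeded_watershed(
    image: np.ndarray,
    seeds,
    ridge_width: int = 3,
    smooth_sigma: float = 1.0,
) -> MembraneMask:
    """Manually-seeded watershed segmentation with a membrane ridge mask.

    The watershed relief is the gradient magnitude of the Gaussian-smoothed
    image, so basins flood from the seeds and meet on intensity ridges — the
    membrane between a cell-interior seed and a background seed.  The
    membrane mask collects pixels within ``ridge_width`` of any boundary
    separating two different labels.

    Parameters
    ----------
    image : 2-D array
    seeds : sequence of ``(row, col, label)``
        At least two seeds with at least two distinct positive labels, e.g.
        one inside a cell and one in the background.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("image must be 2-D")
    seeds = [(int(r), int(c), int(label)) for r, c, label in seeds]
    labels = {label for _, _, label in seeds}
    if len(seeds) < 2 or len(labels) < 2:
        raise ValueError("need at least 2 seeds with at least 2 distinct labels")
    h, w = image.shape
    markers = np.zeros(image.shape, dtype=int)
    for r, c, label in seeds:
        if not (0 <= r < h and 0 <= c < w):
            raise ValueError(f"seed ({r}, {c}) outside image")
        markers[r, c] = label
    relief = filters.sobel(ndi.gaussian_filter(image, smooth_sigma))
    label_map = segmentation.watershed(relief, markers)
    boundary = segmentation.find_boundaries(label_map, mode="thick")
    dist = ndi.distance_transform_edt(~boundary)
    mask = dist < ridge_width
    if not mask.any():
        raise ValueError("empty membrane mask: no inter-label boundary found")
    return MembraneMask(label_map=label_map, mask=mask,
                        ridge_width=int(ridge_width))


def membrane_mean_intensity(
    image: np.ndarray,
    mask,
    background_roi: np.ndarray,
) -> float:
    """Background-corrected mean intensity over a membrane mask.

    The background is the mean intensity over a cell-free region; the result
    is ``mean(image[mask]) - mean(image[background])`` and may legitimately
    be negative for dim membranes.  The background ROI must not intersect
    the mask.
    """
    image = np.asarray(image, dtype=float)
    mask_arr = mask.mask if isinstance(mask, MembraneMask) else np.asarray(mask, bool)
    bg = np.asarray(background_roi, bool)
    if mask_arr.shape != image.shape or bg.shape != image.shape:
        raise ValueError("mask and background ROI must match the image shape")
    if not mask_arr.any():
        raise ValueError("empty membrane mask")
    if not bg.any():
        raise ValueError("empty background ROI")
    if (mask_arr & bg).any():
        raise ValueError("background ROI overlaps the membrane mask")
    return float(image[mask_arr].mean() - image[bg].mean())


def count_bright_spots(
    image: np.ndarray,
    params: SpotParams = SpotParams(),
) -> tuple[int, np.ndarray]:
    """Count punctate bright spots with a fixed operator sequence.

    Pipeline order: Gaussian smoothing -> division by the image maximum ->
    morphological white top-hat with a disk (removes objects larger than the
    spot scale) -> extended-maxima transform at depth ``h_maxima`` -> hole
    filling -> shrinking each connected maxima component to its centroid ->
    enumeration.  Division by the maximum makes the count invariant to
    positive rescaling of the image.

    Returns ``(count, coords)`` where ``coords`` is an ``(n, 2)`` integer
    array of ``(row, col)`` spot centers (ties rounded toward the smaller
    index).  A constant image yields zero spots.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("image must be 2-D")
    if np.ptp(image) == 0:
        return 0, np.empty((0, 2), dtype=int)
    smoothed = ndi.gaussian_filter(image, params.gauss_sigma)
    normalized = smoothed / smoothed.max()
    tophat = morphology.white_tophat(
        normalized, footprint=morphology.disk(params.tophat_radius)
    )
    if np.ptp(tophat) == 0:
        return 0, np.empty((0, 2), dtype=int)
    maxima = morphology.h_maxima(tophat, params.h_maxima)
    maxima = ndi.binary_fill_holes(maxima)
    labeled, n = ndi.label(maxima)
    if n == 0:
        return 0, np.empty((0, 2), dtype=int)
    # centroid per component, half-integer ties rounded toward the smaller index
    coords = np.array(
        [[int(np.ceil(r - 0.5)), int(np.ceil(c - 0.5))]
         for region in measure.regionprops(labeled)
         for r, c in [region.centroid]]
    )
    return int(n), coords


def coloc_pearson(
    channel1: np.ndarray,
    channel2: np.ndarray,
    mask: np.ndarray,
) -> float:
    """Pearson correlation of two channels over a pixel mask.

    Requires at least 10 mask pixels and non-constant signal in both
    channels inside the mask.
    """
    c1 = np.asarray(channel1, dtype=float)
    c2 = np.asarray(channel2, dtype=float)
    m = np.asarray(mask, bool)
    if c1.shape != c2.shape or c1.shape != m.shape:
        raise ValueError("channels and mask must be congruent")
    if m.sum() < 10:
        raise ValueError("need at least 10 mask pixels")
    x, y = c1[m], c2[m]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant channel")
    return float(np.corrcoef(x, y)[0, 1])


def pi_positive_fraction(
    per_cell_intensities,
    threshold_mode: str = "otsu",
    threshold: float | None = None,
) -> float:
    """Fraction of cells whose intensity exceeds a positivity threshold.

    ``threshold_mode="fixed"`` uses the supplied threshold; ``"otsu"``
    derives one from the log-intensities, suited to the bimodal
    positive/negative mixtures produced by a permeabilization dye.
    """
    x = np.asarray(per_cell_intensities, dtype=float)
    if x.size == 0:
        raise ValueError("no cells supplied")
    if threshold_mode == "fixed":
        if threshold is None:
            raise ValueError("fixed mode needs an explicit threshold")
        return float((x > threshold).mean())
    if threshold_mode == "otsu":
        if np.any(x <= 0):
            raise ValueError("otsu-on-log mode needs positive intensities")
        if np.ptp(x) == 0:
            return 0.0
        log_thr = filters.threshold_otsu(np.log(x))
        return float((np.log(x) > log_thr).mean())
    raise ValueError(f"unknown threshold mode {threshold_mode!r}")
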