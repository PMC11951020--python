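"""Lesion segmentation on the normalised amplitude MAP.

Hypopigmented lesions appear as low-amplitude regions of the PA MAP, so
the map is percentile-saturated and normalised to [0, 1], blurred to
avoid an overfitted boundary, and split by Otsu's method; small
connected components in either class are reassigned (outlier removal and
hole filling).  The lesion boundary is traced per component in order,
with outward unit normals estimated from the gradient of the smoothed
mask.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
from scipy import ndimage
from skimage import measure

from .config import PipelineConfig
from .errors import DegenerateInputError

__all__ = [
    "LesionSegmentation",
    "normalize_saturate",
    "otsu_threshold",
    "segment_lesion",
    "rectangular_roi",
    "detect_tape_roi",
    "boundary_pixel_mask",
]

log = logging.getLogger(__name__)


@dataclass
class LesionSegmentation:
    """ROI partition plus ordered lesion boundary with outward normals.

    ``lesion_mask`` and ``normal_mask`` are disjoint and tile ``roi_mask``.
    ``boundary`` lists, per lesion component, an ordered (counter-clockwise)
    ``(n, 2)`` array of (row, col) boundary pixels — lesion pixels
    4-adjacent to normal skin — and ``normals`` the matching unit vectors
    pointing from lesion toward normal skin.  ``lesion_free`` flags scans
    where no credible lesion was found (masks then hold the empty lesion).
    """

    roi_mask: np.ndarray
    lesion_mask: np.ndarray
    normal_mask: np.ndarray
    boundary: List[np.ndarray] = field(default_factory=list)
    normals: List[np.ndarray] = field(default_factory=list)
    threshold_used: float = float("nan")
    lesion_free: bool = False

    def all_boundary(self) -> np.ndarray:
        """All ordered boundary pixels pooled across components, (n, 2)."""
        if not self.boundary:
            return np.zeros((0, 2), dtype=int)
        return np.concatenate(self.boundary, axis=0)

    def all_normals(self) -> np.ndarray:
        if not self.normals:
            return np.zeros((0, 2), dtype=float)
        return np.concatenate(self.normals, axis=0)


def rectangular_roi(shape, margin_px: int) -> np.ndarray:
    """Rectangular ROI inset ``margin_px`` from every image edge."""
    roi = np.zeros(shape, dtype=bool)
    roi[margin_px:shape[0] - margin_px, margin_px:shape[1] - margin_px] = True
    return roi


def detect_tape_roi(amplitude: np.ndarray, frac: float = 0.05,
                    margin_px: int = 2) -> np.ndarray:
    """Auto-detect the tape-marked ROI as the largest non-dark region.

    The marking tape blocks both light and sound, so the covered border
    band carries almost no PA signal.  Pixels above ``frac`` of the map
    maximum are kept, the largest connected region is taken, holes are
    filled and the region eroded by ``margin_px`` to stay clear of the
    tape edge.  For phantoms or manual workflows pass an explicit mask
    instead.
    """
    bright = amplitude > frac * amplitude.max()
    labels = measure.label(bright, connectivity=2)
    if labels.max() == 0:
        raise DegenerateInputError("no signal region found for ROI detection")
    largest = np.argmax(np.bincount(labels.ravel())[1:]) + 1
    roi = ndimage.binary_fill_holes(labels == largest)
    if margin_px > 0:
        roi = ndimage.binary_erosion(roi, iterations=margin_px)
    return roi


def normalize_saturate(amplitude: np.ndarray, roi: np.ndarray,
                       percentiles=(1.0, 99.0)) -> np.ndarray:
    """Saturate to ROI percentiles and map affinely to [0, 1].

    Values at or below the low percentile become 0, at or above the high
    percentile become 1; non-ROI pixels are set to 0.  A constant ROI maps
    to 0.5 everywhere (with a warning).
    """
    amplitude = np.asarray(amplitude, dtype=float)
    roi = np.asarray(roi, dtype=bool)
    vals = amplitude[roi]
    if vals.size == 0:
        raise DegenerateInputError("empty ROI")
    lo, hi = np.percentile(vals, list(percentiles))
    out = np.zeros_like(amplitude)
    if hi <= lo:
        warnings.warn("constant ROI: normalised map set to 0.5", stacklevel=2)
        out[roi] = 0.5
        return out
    out[roi] = np.clip((amplitude[roi] - lo) / (hi - lo), 0.0, 1.0)
    return out


def otsu_threshold(values, n_bins: int = 256) -> float:
    """Otsu's threshold over a histogram of ``n_bins`` bins on [0, 1].

    Returns the bin edge maximising the between-class variance; among
    ties the smallest edge wins.  Values are expected in [0, 1] (the
    output of :func:`normalize_saturate`).
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size < 2 or np.ptp(values) == 0:
        raise DegenerateInputError("need at least two distinct values for Otsu")
    hist, edges = np.histogram(values, bins=n_bins, range=(0.0, 1.0))
    hist = hist.astype(float)
    total = hist.sum()
    centers = 0.5 * (edges[:-1] + edges[1:])
    w0 = np.cumsum(hist)[:-1]
    w1 = total - w0
    m0 = np.cumsum(hist * centers)[:-1]
    m1 = (hist * centers).sum() - m0
    with np.errstate(divide="ignore", invalid="ignore"):
        between = np.where((w0 > 0) & (w1 > 0),
                           w0 * w1 * (m0 / w0 - m1 / w1) ** 2, -np.inf)
    if not np.isfinite(between).any():
        raise DegenerateInputError("all values fall in one histogram bin")
    k = int(np.argmax(between))            # argmax returns the first maximum
    return float(edges[k + 1])


def boundary_pixel_mask(lesion: np.ndarray, normal: np.ndarray) -> np.ndarray:
    """Lesion pixels 4-adjacent to at least one normal-skin pixel."""
    four = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=bool)
    touch = ndimage.binary_dilation(normal, structure=four)
    return lesion & touch


def _ordered_boundary(component: np.ndarray, bmask: np.ndarray) -> np.ndarray:
    """Ordered (CCW) boundary pixels of one component, subset of ``bmask``."""
    contours = measure.find_contours(component.astype(float), 0.5)
    if not contours:
        return np.zeros((0, 2), dtype=int)
    contour = max(contours, key=len)
    # enforce counter-clockwise orientation in (col=x, row=y image coords)
    rr, cc = contour[:, 0], contour[:, 1]
    area2 = np.sum(cc[:-1] * rr[1:] - cc[1:] * rr[:-1])
    if area2 < 0:
        contour = contour[::-1]
    pix = np.round(contour).astype(int)
    pix[:, 0] = np.clip(pix[:, 0], 0, component.shape[0] - 1)
    pix[:, 1] = np.clip(pix[:, 1], 0, component.shape[1] - 1)
    keep = bmask[pix[:, 0], pix[:, 1]]
    pix = pix[keep]
    if pix.size == 0:
        return np.zeros((0, 2), dtype=int)
    # drop duplicates while preserving contour order
    _, first = np.unique(pix, axis=0, return_index=True)
    order = np.zeros(pix.shape[0], dtype=bool)
    order[np.sort(first)] = True
    return pix[order]


def segment_lesion(norm_map: np.ndarray, roi: np.ndarray,
                   cfg: Optional[PipelineConfig] = None) -> LesionSegmentation:
    """Segment the lesion from the normalised amplitude MAP.

    Gaussian blur (``blur_sigma_px``, normalised convolution so non-ROI
    pixels do not bleed in) -> Otsu on ROI values -> lesion = pixels below
    the threshold.  Components of either class smaller than
    ``min_component_px`` (8-connectivity) are reassigned to the other
    (outlier removal / hole filling).  If Otsu degenerates or the class
    contrast is below ``min_contrast`` the scan is flagged lesion-free.
    """
    cfg = cfg or PipelineConfig()
    roi = np.asarray(roi, dtype=bool)
    norm_map = np.asarray(norm_map, dtype=float)

    num = ndimage.gaussian_filter(np.where(roi, norm_map, 0.0), cfg.blur_sigma_px)
    den = ndimage.gaussian_filter(roi.astype(float), cfg.blur_sigma_px)
    blurred = np.where(roi, num / np.maximum(den, 1e-12), 0.0)

    empty = np.zeros_like(roi)

    def _lesion_free(reason: str) -> LesionSegmentation:
        log.info("lesion-free scan: %s", reason)
        return LesionSegmentation(roi_mask=roi, lesion_mask=empty,
                                  normal_mask=roi.copy(), lesion_free=True)

    try:
        thr = otsu_threshold(blurred[roi], cfg.otsu_bins)
    except DegenerateInputError as exc:
        return _lesion_free(str(exc))

    lesion = (blurred < thr) & roi
    normal = roi & ~lesion
    if not lesion.any() or not normal.any():
        return _lesion_free("Otsu produced an empty class")
    contrast = blurred[normal].mean() - blurred[lesion].mean()
    if contrast < cfg.min_contrast:
        return _lesion_free(f"class contrast {contrast:.3f} below "
                            f"{cfg.min_contrast}")

    # outlier removal: small lesion components -> normal, then hole filling
    for _ in range(2):
        labels = measure.label(lesion, connectivity=2)
        counts = np.bincount(labels.ravel())
        small = counts < cfg.min_component_px
        small[0] = False
        lesion &= ~small[labels]
        holes = roi & ~lesion
        labels = measure.label(holes, connectivity=2)
        counts = np.bincount(labels.ravel())
        small = counts < cfg.min_component_px
        small[0] = False
        lesion |= holes & small[labels]
    normal = roi & ~lesion
    if not lesion.any():
        return _lesion_free("no lesion component survived cleaning")

    bmask = boundary_pixel_mask(lesion, normal)
    smooth = ndimage.gaussian_filter(lesion.astype(float),
                                     max(cfg.blur_sigma_px, 1.0))
    gr, gc = np.gradient(smooth)

    boundary: List[np.ndarray] = []
    normals: List[np.ndarray] = []
    labels = measure.label(lesion, connectivity=2)
    for comp_id in range(1, labels.max() + 1):
        pix = _ordered_boundary(labels == comp_id, bmask)
        if pix.shape[0] == 0:
            continue
        # outward = direction of decreasing smoothed mask = -gradient... the
        # gradient points toward increasing mask value (inward), so negate.
        vec = -np.stack([gr[pix[:, 0], pix[:, 1]],
                         gc[pix[:, 0], pix[:, 1]]], axis=1)
        norm = np.linalg.norm(vec, axis=1)
        ok = norm > 1e-9
        pix, vec, norm = pix[ok], vec[ok], norm[ok]
        if pix.shape[0] == 0:
            continue
        boundary.append(pix)
        normals.append(vec / norm[:, None])

    return LesionSegmentation(roi_mask=roi, lesion_mask=lesion,
                              normal_mask=normal, boundary=boundary,
                              normals=normals, threshold_used=thr)
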