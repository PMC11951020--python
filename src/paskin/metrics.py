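"""The four quantitative lesion metrics.

All metrics run on the normalised (but unblurred) amplitude MAP and the
peak-depth map, restricted by the lesion/normal partition of the ROI:

* **mean PA amplitude** — mean normalised amplitude over lesion pixels;
  tracks overall residual pigment.
* **local SD** — mean over interior lesion pixels of the sample SD in a
  square window; tracks pigment heterogeneity ("skip areas").  Windows
  touching the boundary or leaving the lesion are excluded.
* **mean boundary slope** — amplitude difference between a pixel pair
  probed a fixed offset inward/outward along the boundary normal, per mm,
  averaged over the inter-quartile range of all boundary pixels; tracks
  how abruptly pigment returns at the lesion edge.
* **relative peak depth** (d_L - d_N) — mean of the deepest tail of
  lesion peak depths minus the mean of the shallowest tail of normal-skin
  peak depths; tracks dermal signals unmasked by epidermal pigment loss.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from scipy import ndimage

from .config import PipelineConfig
from .errors import UndefinedMetricError
from .projection import MapImages
from .segmentation import LesionSegmentation, boundary_pixel_mask

__all__ = [
    "LesionMetrics",
    "mean_amplitude",
    "local_sd_metric",
    "boundary_slope_metric",
    "peak_depth_metric",
    "compute_metrics",
    "METRIC_COLUMNS",
]

METRIC_COLUMNS = ("mean_amplitude", "local_sd", "mean_slope", "rel_peak_depth_mm")


@dataclass
class LesionMetrics:
    """The four scalar metrics of one lesion plus their intermediates."""

    mean_amplitude: float
    local_sd: float
    mean_slope: float
    rel_peak_depth_mm: float
    d_N_mm: float
    d_L_mm: float
    slope_samples: np.ndarray = field(default_factory=lambda: np.zeros(0))
    n_lesion_px: int = 0
    n_normal_px: int = 0
    n_boundary_px: int = 0
    scan_id: str = ""
    group_label: Optional[str] = None

    def as_dict(self) -> dict:
        return {
            "scan_id": self.scan_id,
            "group_label": self.group_label,
            "mean_amplitude": self.mean_amplitude,
            "local_sd": self.local_sd,
            "mean_slope": self.mean_slope,
            "rel_peak_depth_mm": self.rel_peak_depth_mm,
            "d_N_mm": self.d_N_mm,
            "d_L_mm": self.d_L_mm,
            "n_lesion_px": self.n_lesion_px,
            "n_normal_px": self.n_normal_px,
            "n_boundary_px": self.n_boundary_px,
        }


def mean_amplitude(norm_map: np.ndarray, lesion_mask: np.ndarray) -> float:
    """Mean normalised amplitude over the lesion area."""
    lesion_mask = np.asarray(lesion_mask, dtype=bool)
    if not lesion_mask.any():
        raise UndefinedMetricError("empty lesion mask")
    return float(np.asarray(norm_map, dtype=float)[lesion_mask].mean())


def _sd_filter(img: np.ndarray, window_px: int) -> np.ndarray:
    """Sample SD (ddof=1) in a ``window_px`` square around every pixel."""
    img = np.asarray(img, dtype=float)
    n = window_px * window_px
    m1 = ndimage.uniform_filter(img, size=window_px, mode="reflect")
    m2 = ndimage.uniform_filter(img * img, size=window_px, mode="reflect")
    var = np.clip((m2 - m1 * m1) * (n / (n - 1)), 0.0, None)
    return np.sqrt(var)


def local_sd_metric(norm_map: np.ndarray, lesion_mask: np.ndarray,
                    boundary_mask: np.ndarray, window_px: int = 5) -> float:
    """Mean windowed sample SD over interior lesion pixels.

    Interior pixels are lesion pixels whose full window lies inside the
    lesion and contains no boundary pixel, so edge contrast cannot leak
    into the heterogeneity estimate.
    """
    if window_px % 2 != 1:
        raise ValueError("window_px must be odd")
    lesion_mask = np.asarray(lesion_mask, dtype=bool)
    boundary_mask = np.asarray(boundary_mask, dtype=bool)
    footprint = np.ones((window_px, window_px), dtype=bool)
    interior = ndimage.binary_erosion(lesion_mask, structure=footprint)
    interior &= ~ndimage.binary_dilation(boundary_mask, structure=footprint)
    if not interior.any():
        raise UndefinedMetricError("lesion too small for the SD window")
    sd = _sd_filter(norm_map, window_px)
    return float(sd[interior].mean())


def boundary_slope_metric(norm_map: np.ndarray, seg: LesionSegmentation,
                          offset_px: int = 5,
                          iqr_bounds: Tuple[float, float] = (0.25, 0.75),
                          grid_step_mm: float = 0.1
                          ) -> Tuple[float, np.ndarray]:
    """IQR-trimmed mean of per-boundary-pixel amplitude slopes.

    At each boundary pixel two samples are probed ``offset_px`` pixels
    inward and outward along the unit normal (nearest-pixel rounding);
    pairs whose inward sample is not lesion or whose outward sample is not
    normal skin (or that leave the image) are dropped.  The slope is
    (outward - inward) / (2 * offset_px * grid_step_mm): positive when
    normal skin outranks the lesion.  Samples are pooled over components,
    sorted, and averaged over ranks within the inclusive IQR.
    """
    norm_map = np.asarray(norm_map, dtype=float)
    pix = seg.all_boundary()
    vec = seg.all_normals()
    if pix.shape[0] == 0:
        raise UndefinedMetricError("no boundary pixels")
    outer = np.round(pix + offset_px * vec).astype(int)
    inner = np.round(pix - offset_px * vec).astype(int)
    h, w = norm_map.shape

    def _inb(p):
        return (p[:, 0] >= 0) & (p[:, 0] < h) & (p[:, 1] >= 0) & (p[:, 1] < w)

    ok = _inb(outer) & _inb(inner)
    outer[~ok] = 0
    inner[~ok] = 0
    ok &= seg.lesion_mask[inner[:, 0], inner[:, 1]]
    ok &= seg.normal_mask[outer[:, 0], outer[:, 1]]
    if ok.sum() < 4:
        raise UndefinedMetricError("fewer than 4 usable boundary pixels")
    dist_mm = 2.0 * offset_px * grid_step_mm
    slopes = (norm_map[outer[ok, 0], outer[ok, 1]]
              - norm_map[inner[ok, 0], inner[ok, 1]]) / dist_mm
    slopes = np.sort(slopes)
    n = slopes.size
    rank = np.arange(n) / (n - 1)
    lo, hi = iqr_bounds
    keep = (rank >= lo - 1e-12) & (rank <= hi + 1e-12)
    return float(slopes[keep].mean()), slopes


def peak_depth_metric(depth_mm: np.ndarray, lesion_mask: np.ndarray,
                      normal_mask: np.ndarray, tail_frac: float = 0.15
                      ) -> Tuple[float, float, float]:
    """Relative PA peak depth (d_L - d_N) and its two components.

    d_N is the mean of the ``ceil(tail_frac * n)`` smallest normal-skin
    peak depths (the shallowest, melanin-dominated skin); d_L the mean of
    the ``ceil(tail_frac * n)`` largest lesion peak depths (the deepest
    peaks the pigment loss reveals).
    """
    depth = np.asarray(depth_mm, dtype=float)
    lesion_mask = np.asarray(lesion_mask, dtype=bool)
    normal_mask = np.asarray(normal_mask, dtype=bool)
    if not lesion_mask.any() or not normal_mask.any():
        raise UndefinedMetricError("both masks must be non-empty")
    dn_vals = depth[normal_mask]
    dl_vals = depth[lesion_mask]
    m_n = int(np.ceil(tail_frac * dn_vals.size))
    m_l = int(np.ceil(tail_frac * dl_vals.size))
    d_n = float(np.partition(dn_vals, m_n - 1)[:m_n].mean())
    d_l = float(np.partition(dl_vals, dl_vals.size - m_l)[-m_l:].mean())
    return d_l - d_n, d_n, d_l


def compute_metrics(maps: MapImages, norm_map: np.ndarray,
                    seg: LesionSegmentation,
                    cfg: Optional[PipelineConfig] = None,
                    scan_id: str = "",
                    group_label: Optional[str] = None) -> LesionMetrics:
    """All four metrics of one segmented scan."""
    cfg = cfg or PipelineConfig()
    if seg.lesion_free or not seg.lesion_mask.any():
        raise UndefinedMetricError(f"scan {scan_id or '?'} is lesion-free")
    bmask = boundary_pixel_mask(seg.lesion_mask, seg.normal_mask)
    amp = mean_amplitude(norm_map, seg.lesion_mask)
    sd = local_sd_metric(norm_map, seg.lesion_mask, bmask, cfg.sd_window_px)
    slope, samples = boundary_slope_metric(
        norm_map, seg, cfg.slope_offset_px, cfg.iqr_bounds, maps.grid_step_mm)
    rel, d_n, d_l = peak_depth_metric(
        maps.depth_mm, seg.lesion_mask, seg.normal_mask, cfg.depth_tail_frac)
    return LesionMetrics(
        mean_amplitude=amp, local_sd=sd, mean_slope=slope,
        rel_peak_depth_mm=rel, d_N_mm=d_n, d_L_mm=d_l,
        slope_samples=samples,
        n_lesion_px=int(seg.lesion_mask.sum()),
        n_normal_px=int(seg.normal_mask.sum()),
        n_boundary_px=int(bmask.sum()),
        scan_id=scan_id, group_label=group_label)
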