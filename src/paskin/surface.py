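"""US-guided skin-surface detection and PA skin-layer windowing.

The skin contour is found per US frame by relative thresholding plus
connectivity filtering, then the PA frame is cropped to a fixed depth
window below the contour so that deep dermal signals (blood vessels) do
not contaminate the epidermal melanin quantification.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.ndimage import median_filter
from scipy.signal import medfilt
from skimage import measure

from .config import PipelineConfig
from .errors import GeometryError
from .geometry import ScanGeometry

__all__ = ["SurfaceMap", "detect_surface", "window_pa"]

log = logging.getLogger(__name__)


@dataclass
class SurfaceMap:
    """Detected skin-surface axial index per (frame, lateral column).

    ``surface_idx`` holds axial indices; columns of frames flagged invalid
    in ``frame_valid`` carry no usable surface.  ``window_px`` is filled in
    by :func:`window_pa`.
    """

    surface_idx: np.ndarray                     # int, (n_frames, n_lateral)
    frame_valid: np.ndarray = field(default=None)  # type: ignore[assignment]
    window_px: Optional[int] = None

    def __post_init__(self) -> None:
        self.surface_idx = np.asarray(self.surface_idx, dtype=int)
        if self.frame_valid is None:
            self.frame_valid = np.ones(self.surface_idx.shape[0], dtype=bool)


def _interp_gaps(idx: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Fill invalid columns by 1D linear interpolation (edge = nearest)."""
    if valid.all():
        return idx
    cols = np.arange(idx.size)
    filled = idx.astype(float)
    filled[~valid] = np.interp(cols[~valid], cols[valid], idx[valid].astype(float))
    return np.round(filled).astype(int)


def detect_surface(us: np.ndarray, cfg: PipelineConfig) -> SurfaceMap:
    """Detect the skin surface in each US frame.

    Per frame: pixels at or above ``us_threshold_frac`` of the frame
    maximum are surface candidates; 8-connected components smaller than
    ``min_component_px`` are discarded as speckle outliers; the surface of
    each lateral column is the shallowest surviving candidate.  Columns
    with no candidate, and columns jumping more than ``max_jump_px`` from
    the median-filtered contour, are re-interpolated from their valid
    neighbours.  Frames with no signal at all are flagged invalid.
    """
    us = np.asarray(us)
    if us.ndim != 3 or us.size == 0:
        raise GeometryError("US volume must be a non-empty 3D array")
    n_frames, n_axial, n_lateral = us.shape
    surface = np.zeros((n_frames, n_lateral), dtype=int)
    frame_valid = np.ones(n_frames, dtype=bool)

    for k in range(n_frames):
        # a 3x3 median prefilter suppresses single-pixel speckle spikes so
        # the relative threshold tracks the interface echo, not outliers
        frame = median_filter(us[k], size=3)
        fmax = frame.max()
        if fmax <= 0:
            frame_valid[k] = False
            log.warning("frame %d entirely below threshold; marked invalid", k)
            continue
        mask = frame >= cfg.us_threshold_frac * fmax
        labels = measure.label(mask, connectivity=2)
        counts = np.bincount(labels.ravel())
        small = counts < cfg.min_component_px
        small[0] = True
        mask &= ~small[labels]
        has = mask.any(axis=0)
        if not has.any():
            frame_valid[k] = False
            log.warning("frame %d: no surface component survives; invalid", k)
            continue
        idx = np.where(has, mask.argmax(axis=0), 0)
        idx = _interp_gaps(idx, has)
        # lateral-continuity refinement against a median-filtered contour
        kernel = min(9, n_lateral - (1 - n_lateral % 2))
        if kernel >= 3:
            med = medfilt(idx.astype(float), kernel_size=kernel)
            ok = np.abs(idx - med) <= cfg.max_jump_px
            if not ok.all() and ok.any():
                idx = _interp_gaps(idx, ok)
        surface[k] = idx

    return SurfaceMap(surface_idx=surface, frame_valid=frame_valid)


def window_pa(pa: np.ndarray, surface: SurfaceMap, window_mm: float,
              geometry: ScanGeometry) -> np.ndarray:
    """Zero the PA volume outside ``[surface, surface + window)`` per column.

    ``window_px = round(window_mm / axial_spacing_mm)``; windows running
    past the bottom of the volume are truncated (logged).  Invalid frames
    are zeroed entirely.  The surface map's ``window_px`` field is set as
    a side effect.
    """
    pa = np.asarray(pa)
    window_px = max(1, int(round(window_mm / geometry.axial_spacing_mm)))
    surface.window_px = window_px
    n_frames, n_axial, n_lateral = pa.shape
    s = surface.surface_idx[:, None, :]
    z = np.arange(n_axial)[None, :, None]
    mask = (z >= s) & (z < s + window_px)
    mask &= surface.frame_valid[:, None, None]
    if (surface.surface_idx + window_px > n_axial).any():
        log.info("skin window truncated at the bottom of the volume")
    return np.where(mask, pa, 0.0)
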