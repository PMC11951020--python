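"""Maximum-amplitude and peak-depth projections on a uniform grid.

The windowed PA volume is collapsed along depth into two 2D maps: the
peak amplitude (MAP) and the depth of that peak below the detected skin
surface.  Both live first on the native scan grid — sinusoidal frame
positions along Y, 0.3 mm element pitch along X — and are then resampled
by separable linear interpolation onto a uniform 0.1 mm grid where all
segmentation and metrics run.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
from scipy.interpolate import interp1d

from .errors import GeometryError
from .geometry import ScanGeometry
from .surface import SurfaceMap

__all__ = ["MapImages", "project_maps", "resample_uniform", "build_map_images"]


@dataclass
class MapImages:
    """Uniform-grid projection images.

    ``amplitude`` is the PA maximum-amplitude projection; ``depth_mm`` the
    depth of the PA peak below the detected surface.  Both share the grid
    described by ``grid_origin_mm``/``grid_step_mm`` (axis order Y, X).
    ``valid`` flags pixels whose native column carried any signal.
    """

    amplitude: np.ndarray
    depth_mm: np.ndarray
    grid_origin_mm: Tuple[float, float] = (0.0, 0.0)
    grid_step_mm: float = 0.1
    valid: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.amplitude.shape != self.depth_mm.shape:
            raise GeometryError("amplitude and depth maps must share a shape")
        if self.valid is None:
            self.valid = np.ones(self.amplitude.shape, dtype=bool)


def project_maps(windowed_pa: np.ndarray, surface: SurfaceMap,
                 geometry: ScanGeometry
                 ) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Native-grid peak amplitude and peak depth below the surface.

    ``amplitude(Y, X) = max_Z pa``; ``depth = (argmax_Z - surface) * dz``
    with argmax ties broken toward the shallowest sample.  Columns with no
    signal get amplitude 0, depth 0 and ``valid=False``.
    """
    pa = np.asarray(windowed_pa)
    amplitude = pa.max(axis=1)
    peak_idx = pa.argmax(axis=1)               # first max = shallowest tie
    depth = (peak_idx - surface.surface_idx) * geometry.axial_spacing_mm
    valid = amplitude > 0
    depth = np.where(valid, np.clip(depth, 0.0, None), 0.0)
    return amplitude, depth, valid


def resample_uniform(native_map: np.ndarray, y_positions_mm: np.ndarray,
                     x_positions_mm: np.ndarray, step_mm: float
                     ) -> Tuple[np.ndarray, Tuple[float, float]]:
    """Separable linear resampling of a native (Y, X) map to a uniform grid.

    Interpolates first along Y (the sinusoidal elevational positions),
    then along X (the element pitch), both to ``step_mm``.  The uniform
    grid spans exactly the native extent, so no extrapolation occurs.
    Returns the resampled map and the grid origin (y0, x0).
    """
    y = np.asarray(y_positions_mm, dtype=float)
    x = np.asarray(x_positions_mm, dtype=float)
    if np.any(np.diff(y) <= 0) or np.any(np.diff(x) <= 0):
        raise GeometryError("native grid positions must be strictly increasing")
    native_map = np.asarray(native_map, dtype=float)
    if native_map.shape != (y.size, x.size):
        raise GeometryError("native map shape inconsistent with positions")

    yu = y[0] + step_mm * np.arange(int(round((y[-1] - y[0]) / step_mm)) + 1)
    xu = x[0] + step_mm * np.arange(int(round((x[-1] - x[0]) / step_mm)) + 1)
    yu = np.clip(yu, y[0], y[-1])
    xu = np.clip(xu, x[0], x[-1])

    along_y = interp1d(y, native_map, axis=0, assume_sorted=True)(yu)
    out = interp1d(x, along_y, axis=1, assume_sorted=True)(xu)
    return out, (float(yu[0]), float(xu[0]))


def build_map_images(windowed_pa: np.ndarray, surface: SurfaceMap,
                     geometry: ScanGeometry) -> MapImages:
    """Project and resample in one step, sharing the operator across maps."""
    amp_n, depth_n, valid_n = project_maps(windowed_pa, surface, geometry)
    y = np.asarray(geometry.elevation_positions_mm)
    x = geometry.lateral_positions_mm
    step = geometry.uniform_step_mm
    amp_u, origin = resample_uniform(amp_n, y, x, step)
    depth_u, _ = resample_uniform(depth_n, y, x, step)
    valid_u, _ = resample_uniform(valid_n.astype(float), y, x, step)
    return MapImages(amplitude=np.clip(amp_u, 0.0, None),
                     depth_mm=np.clip(depth_u, 0.0, None),
                     grid_origin_mm=origin, grid_step_mm=step,
                     valid=valid_u >= 0.5)
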