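"""Scan geometry of the handheld 3D PA/US scanner.

A scan is a stack of ``n_frames`` co-registered 2D PA/US frames acquired
along the elevational (Y) axis by a Scotch-yoke stepper, so the frame
positions are *sinusoidally* spaced: dense near the two ends of the sweep
and sparse in the middle.  Each frame is a B-mode-style image indexed
(axial Z, lateral X) with fixed lateral element pitch and axial sample
spacing.  Volumes are therefore indexed ``(frame Y, axial Z, lateral X)``,
all indices 0-based, with depth windows half-open ``[start, stop)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import GeometryError

__all__ = ["ScanGeometry", "elevational_positions"]


def elevational_positions(n_frames: int, span_mm: float) -> np.ndarray:
    """Elevational frame positions of the Scotch-yoke sweep, in mm.

    The yoke converts uniform motor rotation into sinusoidal linear motion,
    so frame ``k`` of ``K`` sits at

        y_k = (span / 2) * (1 - cos(pi * k / (K - 1)))

    i.e. uniform-in-angle samples of a cosine ramp: strictly increasing from
    0 to ``span_mm``, densest at the two ends of the sweep.

    Parameters
    ----------
    n_frames
        Number of frames ``K`` (>= 2).
    span_mm
        Full elevational travel (> 0).

    Returns
    -------
    numpy.ndarray
        ``(K,)`` float array of positions in mm.
    """
    if n_frames < 2:
        raise GeometryError(f"need at least 2 frames, got {n_frames}")
    if span_mm <= 0:
        raise GeometryError(f"elevational span must be positive, got {span_mm}")
    k = np.arange(n_frames, dtype=float)
    y = 0.5 * span_mm * (1.0 - np.cos(np.pi * k / (n_frames - 1)))
    # pin the endpoints exactly despite rounding in cos()
    y[0] = 0.0
    y[-1] = span_mm
    return y


@dataclass
class ScanGeometry:
    """Geometry of one 3D PA/US scan.

    Defaults describe the clinical scanner: an 8.5 MHz 128-element linear
    array with 0.3 mm pitch, 83 frames over a 25.0 mm elevational sweep,
    PA excitation at 680 nm (melanin-dominant), and a 0.1 mm uniform grid
    for resampled projection images.
    """

    n_frames: int = 83
    n_lateral: int = 128
    n_axial: int = 120
    lateral_pitch_mm: float = 0.3
    axial_spacing_mm: float = 0.05
    elevation_span_mm: float = 25.0
    elevation_positions_mm: np.ndarray = field(default=None)  # type: ignore[assignment]
    wavelength_nm: float = 680.0
    uniform_step_mm: float = 0.1

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise GeometryError("n_frames must be >= 2")
        for name in ("lateral_pitch_mm", "axial_spacing_mm", "elevation_span_mm",
                     "uniform_step_mm"):
            if getattr(self, name) <= 0:
                raise GeometryError(f"{name} must be > 0")
        if self.n_lateral < 1 or self.n_axial < 1:
            raise GeometryError("grid dimensions must be positive")
        if self.elevation_positions_mm is None:
            self.elevation_positions_mm = elevational_positions(
                self.n_frames, self.elevation_span_mm)
        else:
            self.elevation_positions_mm = np.asarray(
                self.elevation_positions_mm, dtype=float)
        y = self.elevation_positions_mm
        if y.shape != (self.n_frames,):
            raise GeometryError("elevation_positions_mm length must equal n_frames")
        if not np.all(np.diff(y) > 0):
            raise GeometryError("elevation positions must be strictly increasing")
        if abs(y[0]) > 1e-9 or abs(y[-1] - self.elevation_span_mm) > 1e-9:
            raise GeometryError("elevation positions must run from 0 to the span")

    @property
    def lateral_positions_mm(self) -> np.ndarray:
        """Lateral (X) element positions in mm, starting at 0."""
        return np.arange(self.n_lateral) * self.lateral_pitch_mm

    @property
    def axial_positions_mm(self) -> np.ndarray:
        """Axial (Z) sample depths in mm below the transducer face."""
        return np.arange(self.n_axial) * self.axial_spacing_mm

    @property
    def volume_shape(self) -> tuple[int, int, int]:
        return (self.n_frames, self.n_axial, self.n_lateral)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ScanGeometry):
            return NotImplemented
        scalars = ("n_frames", "n_lateral", "n_axial", "lateral_pitch_mm",
                   "axial_spacing_mm", "elevation_span_mm", "wavelength_nm",
                   "uniform_step_mm")
        return (all(getattr(self, f) == getattr(other, f) for f in scalars)
                and np.array_equal(self.elevation_positions_mm,
                                   other.elevation_positions_mm))
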