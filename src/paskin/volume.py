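"""Co-registered PA/US volume container."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import DataError, FormatError
from .geometry import ScanGeometry

__all__ = ["PaUsVolume"]


@dataclass
class PaUsVolume:
    """One co-registered 3D PA/US scan.

    ``pa`` and ``us`` are non-negative float32 grids indexed
    ``(frame Y, axial Z, lateral X)`` with identical shapes matching the
    geometry.  ``group_label`` carries the clinical group for cohort work
    ("VIT", "IGH", or any other string).
    """

    pa: np.ndarray
    us: np.ndarray
    geometry: ScanGeometry
    scan_id: str = ""
    group_label: Optional[str] = None

    def __post_init__(self) -> None:
        self.pa = np.asarray(self.pa, dtype=np.float32)
        self.us = np.asarray(self.us, dtype=np.float32)
        if self.pa.shape != self.us.shape:
            raise FormatError(
                f"PA shape {self.pa.shape} != US shape {self.us.shape}")
        if self.pa.shape != self.geometry.volume_shape:
            raise FormatError(
                f"volume shape {self.pa.shape} inconsistent with geometry "
                f"{self.geometry.volume_shape}")
        for name, arr in (("pa", self.pa), ("us", self.us)):
            if not np.all(np.isfinite(arr)):
                raise DataError(f"{name} contains non-finite values")
            if arr.min() < 0:
                raise DataError(f"{name} contains negative amplitudes")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PaUsVolume):
            return NotImplemented
        return (np.array_equal(self.pa, other.pa)
                and np.array_equal(self.us, other.us)
                and self.geometry == other.geometry
                and self.scan_id == other.scan_id
                and self.group_label == other.group_label)
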