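"""Pipeline configuration.

Collects every fixed constant of the processing chain in one validated
object so a cohort run is fully described by (scans, config, seed).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Tuple

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """Constants of the quantification pipeline.

    Parameters
    ----------
    us_threshold_frac
        US surface threshold as a fraction of the per-frame maximum.
    min_component_px
        Connected components (8-connectivity) smaller than this are treated
        as outliers, both in US surface candidates and in lesion/normal masks.
    window_mm
        Depth of the skin-layer window retained below the detected surface.
    saturation_percentiles
        (low, high) ROI percentiles, in percent, used to saturate the
        amplitude map before normalising to [0, 1].
    blur_sigma_px
        Gaussian blur applied before Otsu segmentation, in pixels of the
        0.1 mm uniform grid.
    slope_offset_px
        Half-offset of the boundary-slope probe: samples are taken this many
        pixels inward and outward along the boundary normal.
    sd_window_px
        Side of the square window of the local-SD filter (odd).
    depth_tail_frac
        Tail fraction for the peak-depth metric: the shallowest tail of the
        normal area and the deepest tail of the lesion area are averaged.
    iqr_bounds
        Inclusive rank-fraction bounds of the trimmed mean of boundary slopes.
    max_jump_px
        Largest lateral jump of the detected surface tolerated before a
        column is re-interpolated from its neighbours.
    otsu_bins
        Number of equal-width histogram bins over [0, 1] for Otsu's method.
    min_contrast
        Minimum separation of the two Otsu class means (normalised units)
        for a segmentation to count as a real lesion; below it the scan is
        flagged lesion-free.
    roi_margin_mm
        Inset of the default rectangular ROI from the uniform-grid edges.
    continuity_correction
        Whether the large-sample rank-sum test applies a 0.5 continuity
        correction.
    rng_seed
        Seed for any stochastic step (none in the deterministic pipeline;
        kept for report subsampling and forward compatibility).
    """

    us_threshold_frac: float = 0.5
    min_component_px: int = 100
    window_mm: float = 1.0
    saturation_percentiles: Tuple[float, float] = (1.0, 99.0)
    blur_sigma_px: float = 2.0
    slope_offset_px: int = 5
    sd_window_px: int = 5
    depth_tail_frac: float = 0.15
    iqr_bounds: Tuple[float, float] = (0.25, 0.75)
    max_jump_px: int = 10
    otsu_bins: int = 256
    min_contrast: float = 0.4
    roi_margin_mm: float = 2.0
    continuity_correction: bool = True
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.depth_tail_frac < 0.5:
            raise ValueError("depth_tail_frac must lie in (0, 0.5)")
        lo, hi = self.iqr_bounds
        if not lo < hi:
            raise ValueError("iqr_bounds must satisfy lower < upper")
        if self.sd_window_px % 2 != 1:
            raise ValueError("sd_window_px must be odd")
        if not 0 < self.us_threshold_frac <= 1:
            raise ValueError("us_threshold_frac must lie in (0, 1]")
        p_lo, p_hi = self.saturation_percentiles
        if not 0 <= p_lo < p_hi <= 100:
            raise ValueError("saturation_percentiles must satisfy 0 <= low < high <= 100")
        if self.slope_offset_px < 1 or self.min_component_px < 1:
            raise ValueError("pixel counts must be positive")

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["saturation_percentiles"] = list(d["saturation_percentiles"])
        d["iqr_bounds"] = list(d["iqr_bounds"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        for key in ("saturation_percentiles", "iqr_bounds"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)
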