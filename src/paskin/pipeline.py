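"""End-to-end scan analysis: volume in, four metrics out."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .errors import UndefinedMetricError
from .metrics import LesionMetrics, compute_metrics
from .projection import MapImages, build_map_images
from .segmentation import (LesionSegmentation, normalize_saturate,
                           rectangular_roi, segment_lesion)
from .stats import CohortResult, cohort_summary
from .surface import SurfaceMap, detect_surface, window_pa
from .volume import PaUsVolume

__all__ = ["ScanAnalysis", "analyze_scan", "analyze_cohort"]

log = logging.getLogger(__name__)


@dataclass
class ScanAnalysis:
    """All intermediates of one analysed scan."""

    surface: SurfaceMap
    maps: MapImages
    norm_map: np.ndarray
    segmentation: LesionSegmentation
    metrics: Optional[LesionMetrics]     # None for lesion-free scans


def analyze_scan(volume: PaUsVolume, cfg: Optional[PipelineConfig] = None,
                 roi_mask: Optional[np.ndarray] = None) -> ScanAnalysis:
    """Run the full quantification chain on one co-registered scan.

    Surface detection on US -> PA skin-layer windowing -> MAP/peak-depth
    projection -> uniform-grid resampling -> ROI -> normalisation -> Otsu
    segmentation -> metrics.  ``roi_mask`` (uniform grid) overrides the
    default rectangle inset ``roi_margin_mm`` from the grid edges;
    lesion-free scans return ``metrics=None``.
    """
    cfg = cfg or PipelineConfig()
    surface = detect_surface(volume.us, cfg)
    windowed = window_pa(volume.pa, surface, cfg.window_mm, volume.geometry)
    maps = build_map_images(windowed, surface, volume.geometry)
    if roi_mask is None:
        margin_px = int(round(cfg.roi_margin_mm / maps.grid_step_mm))
        roi_mask = rectangular_roi(maps.amplitude.shape, margin_px)
    norm_map = normalize_saturate(maps.amplitude, roi_mask,
                                  cfg.saturation_percentiles)
    seg = segment_lesion(norm_map, roi_mask, cfg)
    metrics: Optional[LesionMetrics] = None
    if not seg.lesion_free:
        try:
            metrics = compute_metrics(maps, norm_map, seg, cfg,
                                      scan_id=volume.scan_id,
                                      group_label=volume.group_label)
        except UndefinedMetricError as exc:
            log.warning("scan %s: metrics undefined (%s)", volume.scan_id, exc)
    return ScanAnalysis(surface=surface, maps=maps, norm_map=norm_map,
                        segmentation=seg, metrics=metrics)


def analyze_cohort(volumes: Iterable[PaUsVolume],
                   cfg: Optional[PipelineConfig] = None) -> CohortResult:
    """Analyse a labelled cohort and summarise it per group.

    Lesion-free or undefined-metric scans are logged and excluded from
    the per-lesion table.
    """
    cfg = cfg or PipelineConfig()
    records = []
    n_skipped = 0
    for volume in volumes:
        analysis = analyze_scan(volume, cfg)
        if analysis.metrics is None:
            n_skipped += 1
            continue
        records.append(analysis.metrics.as_dict())
    if n_skipped:
        log.info("excluded %d lesion-free/undefined scans", n_skipped)
    per_lesion = pd.DataFrame.from_records(records)
    return cohort_summary(per_lesion, continuity=cfg.continuity_correction)
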