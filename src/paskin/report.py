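"""Figure-style outputs: per-scan overlays and metric histograms."""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402

from .pipeline import ScanAnalysis  # noqa: E402
from .stats import CohortResult  # noqa: E402

__all__ = ["scan_overlay_figure", "save_scan_overlay", "save_histograms"]


def scan_overlay_figure(analysis: ScanAnalysis, title: str = ""):
    """Three-panel overlay: MAP + boundary, boundary slope markers, depth map."""
    fig, axes = plt.subplots(1, 3, figsize=(13, 4))
    seg = analysis.segmentation
    extent = None

    ax = axes[0]
    ax.imshow(analysis.norm_map, cmap="magma", extent=extent)
    for pix in seg.boundary:
        ax.plot(pix[:, 1], pix[:, 0], "w.", markersize=1)
    ax.set_title("normalised PA MAP + boundary")

    ax = axes[1]
    ax.imshow(seg.lesion_mask, cmap="gray")
    if analysis.metrics is not None and seg.boundary:
        pix = seg.all_boundary()
        samples = analysis.metrics.slope_samples
        k = min(len(pix), len(samples))
        sc = ax.scatter(pix[:k, 1], pix[:k, 0], c=samples[:k], s=4,
                        cmap="viridis")
        fig.colorbar(sc, ax=ax, label="slope (norm. units / mm)")
    ax.set_title("boundary slope")

    ax = axes[2]
    im = ax.imshow(np.where(seg.roi_mask, analysis.maps.depth_mm, np.nan),
                   cmap="cividis")
    for pix in seg.boundary:
        ax.plot(pix[:, 1], pix[:, 0], "w.", markersize=1)
    fig.colorbar(im, ax=ax, label="PA peak depth (mm)")
    ax.set_title("peak depth")

    if title:
        fig.suptitle(title)
    fig.tight_layout()
    return fig


def save_scan_overlay(analysis: ScanAnalysis, path, title: str = "") -> None:
    fig = scan_overlay_figure(analysis, title)
    fig.savefig(path, dpi=120)
    plt.close(fig)


def save_histograms(result: CohortResult, out_dir,
                    per_lesion: Optional[pd.DataFrame] = None) -> None:
    """Write the 50-bin metric histograms as CSV, one file per metric."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for metric, h in result.histograms.items():
        df = pd.DataFrame({
            "bin_left": h["bin_edges"][:-1],
            "bin_right": h["bin_edges"][1:],
            "count": h["counts"],
        })
        df.to_csv(out_dir / f"hist_{metric}.csv", index=False)
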