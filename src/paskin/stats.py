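"""Group comparison and cohort summaries.

The metrics are not guaranteed normal, so group differences are tested
with the two-sided Wilcoxon rank-sum test: exact by complete enumeration
of rank assignments for small pooled samples, otherwise a tie-corrected
normal approximation with optional continuity correction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations
from math import comb
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm as _normal
from scipy.stats import rankdata

from .errors import DegenerateInputError
from .metrics import METRIC_COLUMNS

__all__ = ["rank_sum_test", "cohort_summary", "CohortResult",
           "EXACT_MAX_POOLED"]

EXACT_MAX_POOLED = 12
_HIST_BINS = 50


def rank_sum_test(x: Sequence[float], y: Sequence[float],
                  continuity: bool = True,
                  exact_max_pooled: int = EXACT_MAX_POOLED) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    For pooled sizes up to ``exact_max_pooled`` the null distribution of
    the rank sum of ``x`` is enumerated completely over all C(n, n_x)
    assignments of the pooled mid-ranks, so ties are handled exactly.
    Larger samples use the normal approximation with tie-corrected
    variance and (optionally) a 0.5 continuity correction.  Two-sided
    p = min(1, 2 * smaller one-sided tail).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise DegenerateInputError("rank-sum test needs two non-empty samples")
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)           # mid-ranks for ties
    w_obs = ranks[: x.size].sum()
    n1, n2 = x.size, y.size
    n = n1 + n2

    if n <= exact_max_pooled:
        total = comb(n, n1)
        eps = 1e-9
        n_le = n_ge = 0
        for idx in combinations(range(n), n1):
            w = ranks[list(idx)].sum()
            if w <= w_obs + eps:
                n_le += 1
            if w >= w_obs - eps:
                n_ge += 1
        one_sided = min(n_le, n_ge) / total
        return min(1.0, 2.0 * one_sided)

    mu = n1 * (n + 1) / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts ** 3 - counts).sum() / (n * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return 1.0
    d = w_obs - mu
    if continuity:
        d -= 0.5 * np.sign(d)
    z = d / np.sqrt(var)
    return float(min(1.0, 2.0 * _normal.sf(abs(z))))


@dataclass
class CohortResult:
    """Per-lesion table, per-group summaries, and per-metric p-values."""

    per_lesion: pd.DataFrame
    group_summary: pd.DataFrame          # index (metric, group) -> mean/sd/n
    p_values: Dict[str, float]           # metric -> two-sided p (NaN if n/a)
    histograms: Dict[str, dict] = field(default_factory=dict)

    def to_csv(self, per_lesion_path, summary_path) -> None:
        self.per_lesion.to_csv(per_lesion_path, index=False)
        self.group_summary.to_csv(summary_path)

    def p_values_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({k: (None if np.isnan(v) else v)
                       for k, v in self.p_values.items()}, fh, indent=2)


def cohort_summary(per_lesion: pd.DataFrame,
                   metrics: Sequence[str] = METRIC_COLUMNS,
                   continuity: bool = True) -> CohortResult:
    """Group means/SDs and rank-sum p per metric from a per-lesion table.

    ``per_lesion`` needs a ``group_label`` column plus the metric columns.
    Undefined (NaN) metric values are excluded pairwise; the p-value is
    only computed when exactly two groups have data for a metric.
    Histograms use 50 bins over each metric's observed range.
    """
    if "group_label" not in per_lesion.columns:
        raise ValueError("per_lesion table needs a group_label column")
    rows = []
    p_values: Dict[str, float] = {}
    histograms: Dict[str, dict] = {}
    for metric in metrics:
        if metric not in per_lesion.columns:
            continue
        sub = per_lesion[["group_label", metric]].dropna()
        groups = sorted(sub["group_label"].unique())
        for gname in groups:
            vals = sub.loc[sub["group_label"] == gname, metric].to_numpy(float)
            rows.append({
                "metric": metric, "group": gname, "n": vals.size,
                "mean": vals.mean() if vals.size else np.nan,
                "sd": vals.std(ddof=1) if vals.size > 1 else np.nan,
            })
        if len(groups) == 2:
            a = sub.loc[sub["group_label"] == groups[0], metric].to_numpy(float)
            b = sub.loc[sub["group_label"] == groups[1], metric].to_numpy(float)
            p_values[metric] = rank_sum_test(a, b, continuity=continuity)
        else:
            p_values[metric] = float("nan")
        all_vals = sub[metric].to_numpy(float)
        if all_vals.size:
            counts, edges = np.histogram(all_vals, bins=_HIST_BINS)
            histograms[metric] = {"counts": counts, "bin_edges": edges}
    summary = pd.DataFrame(rows).set_index(["metric", "group"]) if rows \
        else pd.DataFrame(columns=["metric", "group", "n", "mean", "sd"])
    return CohortResult(per_lesion=per_lesion, group_summary=summary,
                        p_values=p_values, histograms=histograms)
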