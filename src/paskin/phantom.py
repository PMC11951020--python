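"""Synthetic PA/US skin phantoms with ground truth.

The phantom emulates the signal structure the quantification pipeline
relies on, not acoustics:

* a curved skin surface carrying a bright, one-sided US interface echo
  with Rayleigh speckle beneath it;
* an epidermal melanin band just below the surface whose PA amplitude is
  ``melanin_amplitude * pigment_field(X, Y)``;
* a hypopigmented lesion: an ellipse on the (X, Y) plane inside which the
  pigment field drops to ``residual_fraction``, crossed at the rim by a
  logistic ramp whose 10-90% transition width is ``border_width_mm``
  (gradual for vitiligo-like lesions, sharp for IGH-like ones);
* optional focal pigment islands ("skip areas") inside the lesion, drawn
  as a Poisson process with Gaussian radial profiles — the IGH hallmark;
* a dermal vessel stripe at ``vessel_depth_mm`` below the surface whose
  hemoglobin signal becomes the PA peak wherever epidermal melanin falls
  below it;
* additive Gaussian noise on the PA channel (clipped at zero).

Frames are sampled at the Scotch-yoke elevational positions so the
phantom exercises the sinusoidal-to-uniform resampling step.  Everything
is deterministic given ``seed``.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from .geometry import ScanGeometry
from .surface import SurfaceMap
from .volume import PaUsVolume

__all__ = [
    "PhantomConfig",
    "PhantomTruth",
    "generate_phantom",
    "generate_cohort",
    "vitiligo_like_config",
    "igh_like_config",
]

# 10-90% width of the logistic f(d)=1/(1+exp(-d/s)) is 2*ln(9)*s
_LOGISTIC_1090 = 2.0 * np.log(9.0)


@dataclass
class PhantomConfig:
    """Scene description of one synthetic scan.

    Amplitudes are in arbitrary PA units with ``melanin_amplitude`` the
    normal-skin epidermal band; all fractions are relative to it.  The
    lesion is an ellipse with ``lesion_center_mm``/``lesion_semi_axes_mm``
    on the (X, Y) plane in scanner coordinates.
    """

    geometry: ScanGeometry = field(default_factory=ScanGeometry)
    surface_depth_mm: float = 2.0
    surface_curvature_mm: float = 0.6
    epidermis_thickness_mm: float = 0.2
    melanin_amplitude: float = 1.0
    lesion_center_mm: Tuple[float, float] = (19.0, 12.5)  # (X, Y)
    lesion_semi_axes_mm: Tuple[float, float] = (8.0, 6.0)
    residual_fraction: float = 0.1
    border_width_mm: float = 1.0
    island_density_per_cm2: float = 0.0
    island_radius_mm: float = 0.3
    island_amplitude_frac: float = 0.7
    vessel_amplitude_frac: float = 0.2
    vessel_depth_mm: float = 0.6
    noise_sd_frac: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.residual_fraction <= 1.0:
            raise ValueError("residual_fraction must lie in [0, 1]")
        if self.border_width_mm < 0:
            raise ValueError("border_width_mm must be >= 0")
        if self.noise_sd_frac < 0:
            raise ValueError("noise_sd_frac must be >= 0")


@dataclass
class PhantomTruth:
    """Ground truth accompanying a generated phantom."""

    true_surface: SurfaceMap
    true_lesion_mask: np.ndarray  # bool, uniform (Y, X) 0.1 mm grid
    true_border_width_mm: float
    config_echo: PhantomConfig


def _pigment_field(cfg: PhantomConfig, x_mm: np.ndarray,
                   y_mm: np.ndarray, rng: np.random.Generator,
                   islands: Optional[list] = None) -> Tuple[np.ndarray, np.ndarray]:
    """Pigment fraction and lesion mask on the grid x_mm (X) x y_mm (Y).

    Returns arrays shaped (len(y_mm), len(x_mm)).  ``islands`` may carry a
    pre-drawn island list [(x, y, sigma), ...] so native and uniform grids
    see the same scene.
    """
    cx, cy = cfg.lesion_center_mm
    a, b = cfg.lesion_semi_axes_mm
    X, Y = np.meshgrid(x_mm, y_mm)
    dx, dy = X - cx, Y - cy
    r = np.hypot(dx, dy)
    q = np.sqrt((dx / a) ** 2 + (dy / b) ** 2)
    # signed distance along the radial ray: negative inside the ellipse
    with np.errstate(divide="ignore", invalid="ignore"):
        signed_d = np.where(q > 0, r * (1.0 - 1.0 / np.maximum(q, 1e-12)),
                            -min(a, b))
    mask = q < 1.0
    rf = cfg.residual_fraction
    if cfg.border_width_mm > 0:
        s = cfg.border_width_mm / _LOGISTIC_1090
        ramp = 1.0 / (1.0 + np.exp(-signed_d / s))
    else:
        ramp = (signed_d >= 0).astype(float)
    pigment = rf + (1.0 - rf) * ramp
    if islands:
        bump = np.zeros_like(pigment)
        for ix, iy, sigma in islands:
            rr2 = (X - ix) ** 2 + (Y - iy) ** 2
            bump += cfg.island_amplitude_frac * np.exp(-rr2 / (2.0 * sigma ** 2))
        pigment = np.clip(pigment + np.where(mask, bump, 0.0), 0.0, 1.0)
    return pigment, mask


def _draw_islands(cfg: PhantomConfig, rng: np.random.Generator) -> list:
    if cfg.island_density_per_cm2 <= 0:
        return []
    a, b = cfg.lesion_semi_axes_mm
    cx, cy = cfg.lesion_center_mm
    area_cm2 = np.pi * a * b / 100.0
    n = rng.poisson(cfg.island_density_per_cm2 * area_cm2)
    islands = []
    for _ in range(n):
        u, theta = rng.random(), rng.uniform(0, 2 * np.pi)
        x = cx + np.sqrt(u) * a * np.cos(theta)
        y = cy + np.sqrt(u) * b * np.sin(theta)
        sigma = cfg.island_radius_mm * rng.uniform(0.5, 1.5)
        islands.append((x, y, sigma))
    return islands


def generate_phantom(cfg: PhantomConfig) -> Tuple[PaUsVolume, PhantomTruth]:
    """Rasterise one phantom scan plus its ground truth.

    Deterministic given ``cfg.seed``.  If the lesion ellipse extends past
    the scan area a warning is emitted and the scene is clipped.
    """
    g = cfg.geometry
    rng = np.random.default_rng(cfg.seed)
    x = g.lateral_positions_mm                       # (X,)
    y = np.asarray(g.elevation_positions_mm)         # (K,)
    z = g.axial_positions_mm                         # (Z,)

    cx, cy = cfg.lesion_center_mm
    a, b = cfg.lesion_semi_axes_mm
    if (cx - a < x[0] or cx + a > x[-1] or cy - b < y[0] or cy + b > y[-1]):
        warnings.warn("lesion ellipse extends outside the scan area; clipped",
                      stacklevel=2)

    # skin surface depth z_s(X, Y); peak-to-peak undulation = curvature
    X, Y = np.meshgrid(x, y)
    x_span = max(x[-1] - x[0], 1e-9)
    zs = (cfg.surface_depth_mm
          + 0.5 * cfg.surface_curvature_mm
          * np.cos(2 * np.pi * X / x_span) * np.cos(2 * np.pi * Y / g.elevation_span_mm))

    islands = _draw_islands(cfg, rng)
    pigment, _ = _pigment_field(cfg, x, y, rng, islands)

    zz = z[None, :, None]                            # (1, Z, 1)
    zs3 = zs[:, None, :]                             # (K, 1, X)

    # PA: epidermal band (FWHM = epidermis thickness) + dermal vessel stripe
    sigma_e = cfg.epidermis_thickness_mm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    band = np.exp(-((zz - (zs3 + cfg.epidermis_thickness_mm / 2.0)) ** 2)
                  / (2.0 * sigma_e ** 2))
    pa = cfg.melanin_amplitude * pigment[:, None, :] * band
    sigma_v = 0.06
    vessel = np.exp(-((zz - (zs3 + cfg.vessel_depth_mm)) ** 2)
                    / (2.0 * sigma_v ** 2))
    pa = pa + cfg.melanin_amplitude * cfg.vessel_amplitude_frac * vessel
    if cfg.noise_sd_frac > 0:
        pa = pa + rng.normal(0.0, cfg.noise_sd_frac * cfg.melanin_amplitude,
                             size=pa.shape)
    pa = np.clip(pa, 0.0, None)

    # US: one-sided interface echo starting at the surface, speckle below.
    # Echo peak is 3x the speckle mean so the contour is detectable but not
    # trivially the frame maximum.
    echo_sigma = 0.1
    inside = zz >= zs3
    us = np.where(inside,
                  np.exp(-((zz - zs3) ** 2) / (2.0 * echo_sigma ** 2)), 0.0)
    if cfg.noise_sd_frac > 0:
        speckle_scale = (1.0 / 3.0) / np.sqrt(np.pi / 2.0)
        speckle = rng.rayleigh(speckle_scale, size=us.shape)
        us = us + np.where(inside, speckle, 0.0)
    us = np.clip(us, 0.0, None)

    # ground truth: first axial sample at or below the interface
    surf_idx = np.ceil(zs / g.axial_spacing_mm - 1e-9).astype(int)
    surf_idx = np.clip(surf_idx, 0, g.n_axial - 1)
    truth_surface = SurfaceMap(surface_idx=surf_idx,
                               frame_valid=np.ones(g.n_frames, dtype=bool))

    step = g.uniform_step_mm
    xu = x[0] + step * np.arange(int(round((x[-1] - x[0]) / step)) + 1)
    yu = y[0] + step * np.arange(int(round((y[-1] - y[0]) / step)) + 1)
    _, mask_u = _pigment_field(cfg, xu, yu, rng, None)

    volume = PaUsVolume(pa=pa, us=us, geometry=g, scan_id=f"phantom-{cfg.seed}")
    truth = PhantomTruth(true_surface=truth_surface, true_lesion_mask=mask_u,
                         true_border_width_mm=cfg.border_width_mm,
                         config_echo=cfg)
    return volume, truth


def vitiligo_like_config(seed: int = 0, **overrides) -> PhantomConfig:
    """Vitiligo-like lesion: near-total pigment loss, gradual border, no islands.

    The wide logistic border models partial melanocyte presence along the
    margin; the low residual fraction lets the dermal vessel become the PA
    peak inside the lesion, pushing the peak depth down.
    """
    base = dict(residual_fraction=0.08, border_width_mm=4.0,
                island_density_per_cm2=0.0, seed=seed)
    base.update(overrides)
    return PhantomConfig(**base)


def igh_like_config(seed: int = 0, **overrides) -> PhantomConfig:
    """IGH-like lesion: sharp border, moderate residual pigment, skip areas.

    Focal pigment islands (Poisson-placed Gaussian bumps) reproduce the
    heterogeneous "skip area" texture; the residual epidermal band stays
    above the vessel amplitude so the PA peak remains shallow.
    """
    base = dict(residual_fraction=0.35, border_width_mm=0.3,
                island_density_per_cm2=6.0, island_radius_mm=0.35,
                island_amplitude_frac=0.7, seed=seed)
    base.update(overrides)
    return PhantomConfig(**base)


def generate_cohort(vit_cfg: PhantomConfig, igh_cfg: PhantomConfig,
                    n_vit: int, n_igh: int, seed: int
                    ) -> List[Tuple[PaUsVolume, PhantomTruth]]:
    """Generate a labelled two-group cohort with per-scan jitter.

    Per-scan seeds are spawned reproducibly from the master ``seed``; each
    scan jitters the lesion centre (+-1.5 mm) and semi-axes (+-15%) of its
    group template.  Scans are labelled "VIT"/"IGH" and returned as
    (volume, truth) pairs, vitiligo first.
    """
    if n_vit < 0 or n_igh < 0:
        raise ValueError("group sizes must be non-negative")
    children = np.random.SeedSequence(seed).spawn(n_vit + n_igh)
    scans: List[Tuple[PaUsVolume, PhantomTruth]] = []
    templates = [("VIT", vit_cfg)] * n_vit + [("IGH", igh_cfg)] * n_igh
    for i, ((label, template), child) in enumerate(zip(templates, children)):
        jit = np.random.default_rng(child)
        cx, cy = template.lesion_center_mm
        a, b = template.lesion_semi_axes_mm
        cfg = dataclasses.replace(
            template,
            lesion_center_mm=(cx + jit.uniform(-1.5, 1.5),
                              cy + jit.uniform(-1.5, 1.5)),
            lesion_semi_axes_mm=(a * jit.uniform(0.85, 1.15),
                                 b * jit.uniform(0.85, 1.15)),
            seed=int(child.generate_state(1)[0] % (2 ** 31)),
        )
        volume, truth = generate_phantom(cfg)
        volume.scan_id = f"{label}{i:03d}"
        volume.group_label = label
        scans.append((volume, truth))
    return scans
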