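"""Normalisation, Otsu thresholding, and lesion segmentation."""

import dataclasses

import numpy as np
import pytest
from skimage.metrics import hausdorff_distance

from paskin import (DegenerateInputError, PipelineConfig, analyze_scan,
                    boundary_pixel_mask, generate_phantom, normalize_saturate,
                    otsu_threshold, segment_lesion)


def exhaustive_otsu(values, n_bins=256):
    """Independent oracle: try every bin edge, recompute class stats."""
    values = np.asarray(values, dtype=float).ravel()
    hist, edges = np.histogram(values, bins=n_bins, range=(0.0, 1.0))
    centers = 0.5 * (edges[:-1] + edges[1:])
    best_k, best_var = None, -np.inf
    for k in range(1, n_bins):
        w0, w1 = hist[:k].sum(), hist[k:].sum()
        if w0 == 0 or w1 == 0:
            continue
        m0 = (hist[:k] * centers[:k]).sum() / w0
        m1 = (hist[k:] * centers[k:]).sum() / w1
        var = w0 * w1 * (m0 - m1) ** 2
        if var > best_var + 1e-12:          # strict: ties keep smallest edge
            best_var, best_k = var, k
    return edges[best_k]


class TestNormalizeSaturate:
    def test_affine_map_midpoint(self):
        amp = np.linspace(0, 100, 10000).reshape(100, 100)
        roi = np.ones_like(amp, dtype=bool)
        out = normalize_saturate(amp, roi, (1.0, 99.0))
        mid = out[np.isclose(amp, 50.0, atol=0.01)]
        assert np.allclose(mid, 0.5, atol=0.01)

    def test_clipping_and_range(self, rng):
        amp = rng.normal(10, 3, (50, 50))
        roi = np.ones_like(amp, dtype=bool)
        out = normalize_saturate(amp, roi, (5.0, 95.0))
        lo = np.percentile(amp, 5.0)
        assert np.all(out[amp < lo] == 0.0)
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_non_roi_zeroed(self, rng):
        amp = rng.random((20, 20)) + 1.0
        roi = np.zeros_like(amp, dtype=bool)
        roi[5:15, 5:15] = True
        out = normalize_saturate(amp, roi)
        assert np.all(out[~roi] == 0.0)

    def test_constant_roi_warns_half(self):
        amp = np.full((10, 10), 2.0)
        roi = np.ones_like(amp, dtype=bool)
        with pytest.warns(UserWarning):
            out = normalize_saturate(amp, roi)
        assert np.all(out == 0.5)


class TestOtsu:
    def test_two_mode_histogram_smallest_optimal_edge(self):
        values = np.r_[np.full(100, 0.2), np.full(100, 0.9)]
        thr = otsu_threshold(values, 256)
        assert thr == exhaustive_otsu(values)
        # any split between the modes is optimal; smallest edge just above 0.2
        assert 0.2 < thr <= 0.2 + 1.0 / 256 + 1e-12

    def test_three_level_splits_heavy_modes(self):
        values = np.r_[np.full(50, 0.1), np.full(10, 0.5), np.full(50, 0.9)]
        thr = otsu_threshold(values, 256)
        assert thr == exhaustive_otsu(values)
        assert 0.1 < thr < 0.9

    def test_duplication_invariance(self, rng):
        values = rng.random(500)
        assert otsu_threshold(values) == otsu_threshold(np.r_[values, values])

    def test_degenerate_input_rejected(self):
        with pytest.raises(DegenerateInputError):
            otsu_threshold(np.full(100, 0.4))

    def test_matches_exhaustive_oracle_on_random_inputs(self, rng):
        for _ in range(20):
            values = np.clip(rng.beta(rng.uniform(0.5, 3), rng.uniform(0.5, 3),
                                      size=rng.integers(50, 400)), 0, 1)
            if np.ptp(values) == 0:
                continue
            assert otsu_threshold(values) == exhaustive_otsu(values)


class TestSegmentLesion:
    def test_phantom_boundary_hausdorff_within_3px(self, small_phantom_config):
        cfg = dataclasses.replace(small_phantom_config, border_width_mm=0.1)
        volume, truth = generate_phantom(cfg)
        analysis = analyze_scan(volume, PipelineConfig(min_component_px=50))
        seg = analysis.segmentation
        assert not seg.lesion_free
        det_b = boundary_pixel_mask(seg.lesion_mask, seg.normal_mask)
        true_lesion = truth.true_lesion_mask
        true_b = true_lesion & ~np.roll(true_lesion, 1, 0) | \
            true_lesion & ~np.roll(true_lesion, -1, 0) | \
            true_lesion & ~np.roll(true_lesion, 1, 1) | \
            true_lesion & ~np.roll(true_lesion, -1, 1)
        assert hausdorff_distance(det_b, true_b) <= 3.0

    def test_contrast_free_scan_flagged_lesion_free(self, small_phantom_config):
        cfg = dataclasses.replace(small_phantom_config, residual_fraction=1.0,
                                  noise_sd_frac=0.02)
        volume, _ = generate_phantom(cfg)
        analysis = analyze_scan(volume, PipelineConfig(min_component_px=50))
        assert analysis.segmentation.lesion_free
        assert analysis.metrics is None

    def test_small_dark_speckle_absorbed(self, rng):
        norm = np.full((80, 80), 0.9)
        norm[20:50, 20:50] = 0.05                  # real lesion, 900 px
        norm[65:67, 65:67] = 0.05                  # 4 px speckle
        roi = np.ones_like(norm, dtype=bool)
        seg = segment_lesion(norm, roi, PipelineConfig(min_component_px=50,
                                                       blur_sigma_px=0.5))
        assert not seg.lesion_mask[65, 65]
        assert seg.lesion_mask[35, 35]

    def test_partition_invariant(self, noisy_small_config):
        volume, _ = generate_phantom(noisy_small_config)
        analysis = analyze_scan(volume, PipelineConfig(min_component_px=50))
        seg = analysis.segmentation
        assert not np.any(seg.lesion_mask & seg.normal_mask)
        assert np.array_equal(seg.lesion_mask | seg.normal_mask, seg.roi_mask)

    def test_affine_rescale_invariance(self, noisy_small_config):
        volume, _ = generate_phantom(noisy_small_config)
        cfg = PipelineConfig(min_component_px=50)
        a1 = analyze_scan(volume, cfg)
        rescaled = dataclasses.replace(
            volume, pa=3.7 * volume.pa + 0.0, us=volume.us)
        rescaled.pa = rescaled.pa.astype(np.float32)
        a2 = analyze_scan(rescaled, cfg)
        assert np.array_equal(a1.segmentation.lesion_mask,
                              a2.segmentation.lesion_mask)

    @pytest.mark.parametrize("residual", [0.0, 0.1, 0.2])
    def test_area_recovery_within_15pct(self, small_phantom_config, residual):
        cfg = dataclasses.replace(small_phantom_config,
                                  residual_fraction=residual,
                                  border_width_mm=0.5, noise_sd_frac=0.05)
        volume, truth = generate_phantom(cfg)
        analysis = analyze_scan(volume, PipelineConfig(min_component_px=50))
        det = analysis.segmentation.lesion_mask.sum()
        true = truth.true_lesion_mask.sum()
        assert abs(det - true) / true <= 0.15

    def test_boundary_pixels_are_lesion_touching_normal(self,
                                                        noisy_small_config):
        volume, _ = generate_phantom(noisy_small_config)
        seg = analyze_scan(volume, PipelineConfig(min_component_px=50)).segmentation
        bmask = boundary_pixel_mask(seg.lesion_mask, seg.normal_mask)
        pix = seg.all_boundary()
        assert pix.shape[0] > 0
        assert bmask[pix[:, 0], pix[:, 1]].all()
        norms = np.linalg.norm(seg.all_normals(), axis=1)
        assert np.allclose(norms, 1.0, atol=1e-6)
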