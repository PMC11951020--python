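"""The four lesion metrics against closed forms and brute-force oracles."""

import dataclasses

import numpy as np
import pytest

from paskin import (LesionSegmentation, PipelineConfig, UndefinedMetricError,
                    analyze_scan, boundary_slope_metric, generate_phantom,
                    local_sd_metric, mean_amplitude, peak_depth_metric)


def naive_sd_image(img, w):
    """Double-loop windowed sample-SD oracle (reflect padding)."""
    r = w // 2
    padded = np.pad(img, r, mode="symmetric")
    out = np.zeros_like(img, dtype=float)
    for i in range(img.shape[0]):
        for j in range(img.shape[1]):
            out[i, j] = np.std(padded[i:i + w, j:j + w], ddof=1)
    return out


def straight_edge_segmentation(shape, edge_col, lesion_side="left"):
    """Manual segmentation with a vertical boundary and horizontal normals."""
    roi = np.ones(shape, dtype=bool)
    lesion = np.zeros(shape, dtype=bool)
    if lesion_side == "left":
        lesion[:, :edge_col + 1] = True
        normal_vec = np.array([0.0, 1.0])
        bcol = edge_col
    else:
        lesion[:, edge_col:] = True
        normal_vec = np.array([0.0, -1.0])
        bcol = edge_col
    rows = np.arange(8, shape[0] - 8)
    boundary = np.stack([rows, np.full_like(rows, bcol)], axis=1)
    normals = np.tile(normal_vec, (rows.size, 1))
    return LesionSegmentation(roi_mask=roi, lesion_mask=lesion,
                              normal_mask=roi & ~lesion,
                              boundary=[boundary], normals=[normals],
                              threshold_used=0.5)


class TestMeanAmplitude:
    def test_direct_mean(self):
        norm = np.zeros((3, 3))
        norm[0] = [0.1, 0.2, 0.3]
        mask = np.zeros((3, 3), dtype=bool)
        mask[0] = True
        assert mean_amplitude(norm, mask) == pytest.approx(0.2)

    def test_constant_region(self):
        norm = np.full((4, 4), 0.25)
        assert mean_amplitude(norm, np.ones((4, 4), bool)) == 0.25

    def test_empty_mask_undefined(self):
        with pytest.raises(UndefinedMetricError):
            mean_amplitude(np.ones((4, 4)), np.zeros((4, 4), bool))

    def test_pigment_island_raises_mean(self):
        base = np.full((30, 30), 0.1)
        mask = np.ones((30, 30), bool)
        with_island = base.copy()
        with_island[10:15, 10:15] = 0.8
        assert mean_amplitude(with_island, mask) > mean_amplitude(base, mask)


class TestLocalSd:
    def test_constant_lesion_zero(self):
        norm = np.full((20, 20), 0.3)
        lesion = np.zeros((20, 20), bool)
        lesion[5:15, 5:15] = True
        assert local_sd_metric(norm, lesion, np.zeros_like(lesion), 5) == 0.0

    def test_single_spike_window_sd(self):
        # 24 zeros and one 1: var = (1 - 1/25) / 24 = 0.04, SD = 0.2
        norm = np.zeros((11, 11))
        norm[5, 5] = 1.0
        lesion = np.zeros((11, 11), bool)
        lesion[3:8, 3:8] = True                     # interior = pixel (5, 5)
        val = local_sd_metric(norm, lesion, np.zeros_like(lesion), 5)
        assert val == pytest.approx(0.2, abs=1e-12)

    def test_matches_naive_oracle(self, rng):
        img = rng.random((30, 30))
        from paskin.metrics import _sd_filter
        assert np.allclose(_sd_filter(img, 5), naive_sd_image(img, 5),
                           atol=1e-9)

    def test_lesion_too_small_undefined(self):
        lesion = np.zeros((10, 10), bool)
        lesion[4:6, 4:6] = True
        with pytest.raises(UndefinedMetricError):
            local_sd_metric(np.ones((10, 10)), lesion,
                            np.zeros_like(lesion), 5)


class TestBoundarySlope:
    def test_ideal_step_edge(self):
        norm = np.where(np.arange(40)[None, :] <= 19, 0.1, 0.8) * np.ones((40, 1))
        seg = straight_edge_segmentation((40, 40), 19, "left")
        slope, samples = boundary_slope_metric(norm, seg, offset_px=5,
                                               grid_step_mm=0.1)
        assert slope == pytest.approx(0.7)
        assert np.allclose(samples, 0.7)

    def test_uniform_map_zero(self):
        norm = np.full((40, 40), 0.5)
        seg = straight_edge_segmentation((40, 40), 19, "left")
        slope, _ = boundary_slope_metric(norm, seg)
        assert slope == 0.0

    def test_linear_ramp_recovers_gradient(self):
        g_per_mm = 0.42
        cols_mm = np.arange(40) * 0.1
        norm = np.tile(g_per_mm * cols_mm, (40, 1))
        seg = straight_edge_segmentation((40, 40), 19, "left")
        slope, _ = boundary_slope_metric(norm, seg, grid_step_mm=0.1)
        assert slope == pytest.approx(g_per_mm, rel=0.05)

    def test_antisymmetric_under_role_swap(self):
        norm = np.where(np.arange(40)[None, :] <= 19, 0.1, 0.8) * np.ones((40, 1))
        left = straight_edge_segmentation((40, 40), 19, "left")
        right = straight_edge_segmentation((40, 40), 20, "right")
        s_left, _ = boundary_slope_metric(norm, left)
        s_right, _ = boundary_slope_metric(norm, right)
        assert s_left == pytest.approx(0.7)
        assert s_right == pytest.approx(-0.7)

    def test_too_few_boundary_pixels_undefined(self):
        seg = straight_edge_segmentation((40, 40), 19, "left")
        seg.boundary = [seg.boundary[0][:2]]
        seg.normals = [seg.normals[0][:2]]
        with pytest.raises(UndefinedMetricError):
            boundary_slope_metric(np.ones((40, 40)), seg)


class TestPeakDepth:
    def test_constructed_tails(self):
        depth = np.zeros((20, 20))
        lesion = np.zeros((20, 20), bool)
        normal = np.zeros((20, 20), bool)
        lesion[:5, :20] = True                      # 100 lesion px
        depth[:5, :20] = 0.2
        depth[0, :15] = 0.9                         # deepest 15 px
        normal[10:15, :20] = True                   # 100 normal px
        depth[10:15, :20] = 0.15
        rel, d_n, d_l = peak_depth_metric(depth, lesion, normal, 0.15)
        assert d_l == pytest.approx(0.9)
        assert d_n == pytest.approx(0.15)
        assert rel == pytest.approx(0.75)

    def test_identical_constant_depth_zero(self):
        depth = np.full((10, 10), 0.4)
        lesion = np.zeros((10, 10), bool)
        lesion[:5] = True
        rel, _, _ = peak_depth_metric(depth, lesion, ~lesion, 0.15)
        assert rel == 0.0

    def test_matches_full_sort_oracle(self, rng):
        depth = rng.random((40, 40))
        lesion = rng.random((40, 40)) < 0.3
        normal = ~lesion
        rel, d_n, d_l = peak_depth_metric(depth, lesion, normal, 0.15)
        dn_vals = np.sort(depth[normal])
        dl_vals = np.sort(depth[lesion])
        m_n = int(np.ceil(0.15 * dn_vals.size))
        m_l = int(np.ceil(0.15 * dl_vals.size))
        assert d_n == pytest.approx(dn_vals[:m_n].mean(), abs=1e-9)
        assert d_l == pytest.approx(dl_vals[-m_l:].mean(), abs=1e-9)
        assert rel == pytest.approx(d_l - d_n, abs=1e-12)

    def test_empty_mask_undefined(self):
        with pytest.raises(UndefinedMetricError):
            peak_depth_metric(np.ones((5, 5)), np.zeros((5, 5), bool),
                              np.ones((5, 5), bool))


class TestPhantomMonotonicity:
    """Scene parameters move the metrics the way the physiology predicts."""

    def _metrics(self, cfg):
        volume, _ = generate_phantom(cfg)
        analysis = analyze_scan(volume, PipelineConfig(min_component_px=50))
        assert analysis.metrics is not None
        return analysis.metrics

    def test_wider_border_lowers_slope(self, noisy_small_config):
        seeds = (1, 2, 3)
        sharp = np.mean([self._metrics(dataclasses.replace(
            noisy_small_config, border_width_mm=0.3, seed=s)).mean_slope
            for s in seeds])
        wide = np.mean([self._metrics(dataclasses.replace(
            noisy_small_config, border_width_mm=3.0, seed=s)).mean_slope
            for s in seeds])
        assert wide < sharp

    def test_islands_raise_local_sd(self, noisy_small_config):
        seeds = (1, 2, 3)
        base = dataclasses.replace(noisy_small_config, residual_fraction=0.35)
        plain = np.mean([self._metrics(dataclasses.replace(
            base, seed=s)).local_sd for s in seeds])
        spotted = np.mean([self._metrics(dataclasses.replace(
            base, island_density_per_cm2=8.0, seed=s)).local_sd
            for s in seeds])
        assert spotted > plain

    def test_pigment_loss_deepens_peak(self, noisy_small_config):
        seeds = (1, 2, 3)
        retained = np.mean([self._metrics(dataclasses.replace(
            noisy_small_config, residual_fraction=0.5, seed=s)).rel_peak_depth_mm
            for s in seeds])
        depleted = np.mean([self._metrics(dataclasses.replace(
            noisy_small_config, residual_fraction=0.05, seed=s)).rel_peak_depth_mm
            for s in seeds])
        assert depleted > retained

    def test_metrics_deterministic(self, noisy_small_config):
        m1 = self._metrics(noisy_small_config)
        m2 = self._metrics(noisy_small_config)
        assert m1.as_dict() == m2.as_dict()
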