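import dataclasses

import numpy as np
import pytest

from paskin import PhantomConfig, ScanGeometry


@pytest.fixture(scope="session")
def small_geometry():
    """Reduced scan geometry for fast pipeline tests."""
    return ScanGeometry(n_frames=31, n_lateral=96, n_axial=100,
                        elevation_span_mm=12.0)


@pytest.fixture(scope="session")
def small_phantom_config(small_geometry):
    """Clean (noise-free, flat-surface) phantom on the small geometry."""
    return PhantomConfig(
        geometry=small_geometry,
        surface_depth_mm=2.0,
        surface_curvature_mm=0.0,
        lesion_center_mm=(14.0, 6.0),
        lesion_semi_axes_mm=(5.0, 3.0),
        residual_fraction=0.1,
        border_width_mm=0.3,
        noise_sd_frac=0.0,
        seed=11,
    )


@pytest.fixture
def noisy_small_config(small_phantom_config):
    return dataclasses.replace(small_phantom_config, noise_sd_frac=0.02,
                               surface_curvature_mm=0.4)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
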