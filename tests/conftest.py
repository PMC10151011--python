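import numpy as np
import pytest

from gastromotil.phantom import PhantomConfig, contour_series, render_series
from gastromotil.pipeline import extract_maps


@pytest.fixture(scope="session")
def static_output():
    """Rendered phantom with all dynamics off (no waves/breathing/noise)."""
    cfg = PhantomConfig.test_scale(frames=8, wave_amplitude_mm=0.0,
                                   breathing_amplitude=(0.0, 0.0, 0.0),
                                   noise_sigma=0.0)
    return render_series(cfg)


@pytest.fixture(scope="session")
def breathing_output():
    """Rendered phantom with breathing and noise but no peristalsis."""
    cfg = PhantomConfig.test_scale(frames=30, wave_amplitude_mm=0.0, seed=3)
    return render_series(cfg)


@pytest.fixture(scope="session")
def wave_maps():
    """Contraction maps from the default study-scale phantom (contours only)."""
    cfg = PhantomConfig(noise_sigma=0.0)
    pairs = contour_series(cfg)
    return cfg, extract_maps(pairs, cfg.frame_interval_s)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
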