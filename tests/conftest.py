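import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_scene():
    """A tiny deterministic scene: two flicker squares, no noise."""
    import nestflick as nf
    return nf.SceneConfig(
        grid_rows=6, grid_cols=8, n_frames=400, square_px=10, fps=50.0,
        noise_sd=0.0,
        cohorts=(nf.CohortSpec(squares=((1, 1), (4, 6)), flicker_rate=0.3),),
        seed=42)
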