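import numpy as np
import pytest

from vorx.signal_sim import SimConfig


@pytest.fixture
def noise_free():
    """Factory for fully deterministic trial configs (no noise/jitter/drift/decay)."""

    def make(goal_bpm: float, duration_s: float = 30.0, **kw) -> SimConfig:
        defaults = dict(
            goal_bpm=goal_bpm,
            duration_s=duration_s,
            amplitude_deg=15.0,
            amplitude_decay_per_bpm=0.0,
            nominal_fps=30.0,
            frame_jitter_sd_s=0.0,
            angle_noise_sd_deg=0.0,
            speed_drift_sd_bpm=0.0,
            dc_offset_deg=0.0,
            seed=0,
        )
        defaults.update(kw)
        return SimConfig(**defaults)

    return make


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
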