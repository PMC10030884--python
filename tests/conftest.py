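"""Shared fixtures: small synthetic recordings with known ground truth."""

import numpy as np
import pytest

from azping import AZSet, SimConfig, generate_movie


@pytest.fixture(scope="session")
def single_event_movie():
    """One AZ, one injected spontaneous event, no noise, no bleach."""
    cfg = SimConfig(
        image_height=48, image_width=48, n_frames=60, n_az=1,
        spont_rate=0.0, evoked_prob=0.0, noise_sd=0.0, bleach_slope=0.0,
        amp_mean=500.0, amp_sd=0.0,
        injected_events=[(0, 20, 500.0, "spontaneous")], seed=5,
    )
    movie, truth = generate_movie(cfg)
    return cfg, movie, truth


@pytest.fixture(scope="session")
def noisy_activity_movie():
    """A realistic small spontaneous recording with transients and noise."""
    cfg = SimConfig(
        image_height=96, image_width=96, n_frames=600, n_az=8,
        spont_rate=0.08, noise_sd=60.0, amp_mean=480.0, amp_sd=120.0, seed=3,
    )
    movie, truth = generate_movie(cfg)
    az = AZSet(truth.az_centers, pixel_size=cfg.pixel_size)
    return cfg, movie, truth, az


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
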