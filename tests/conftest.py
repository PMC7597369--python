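import numpy as np
import pytest

from holotrack import SimConfig, ExpMixture, OrderProbs


@pytest.fixture
def clean_config():
    """Small, observation-noise-free configuration for exact checks."""
    return SimConfig(
        n_events_per_channel=200,
        hub_count=0,
        coloc_fraction=0.0,
        label_fraction_per_channel=(1.0, 1.0),
        bleach_tau_per_channel=(1e12, 1e12),
        loc_noise_sigma=0.0,
        blink_gap_prob=0.0,
        seed=11,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_track(track_id, channel, times, x, y, frame_interval=1.0, frames=None):
    """Construct a Track from explicit localization times and positions."""
    from holotrack import Localization, Track

    times = np.asarray(times, dtype=float)
    x = np.broadcast_to(np.asarray(x, dtype=float), times.shape)
    y = np.broadcast_to(np.asarray(y, dtype=float), times.shape)
    if frames is None:
        frames = np.round(times / frame_interval).astype(int)
    locs = [
        Localization(channel=channel, frame=int(f), t=float(t), x=float(xi),
                     y=float(yi), intensity=1000.0)
        for f, t, xi, yi in zip(frames, times, x, y)
    ]
    return Track(id=track_id, channel=channel, localizations=locs,
                 frame_interval=frame_interval)
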