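import warnings

import numpy as np
import pandas as pd
import pytest

from finwake.io import BODYPARTS, PoseTrack, TrialMeta

warnings.filterwarnings("ignore", message="bandpass high edge")


@pytest.fixture
def meta() -> TrialMeta:
    return TrialMeta(body_length_L=21.7, flow_speed_U=65.0, cylinder_diameter_D=5.0,
                     frame_rate=150.0, emg_rate=4000.0, fish_id="f1", trial_id="t1")


def make_track(parts: dict, n_frames: int, frame_rate: float = 150.0,
               likelihood: float = 1.0) -> PoseTrack:
    """Build a PoseTrack from per-part coordinate arrays (or constants);
    unspecified bodyparts sit at distinct static positions."""
    cols = {}
    for k, part in enumerate(BODYPARTS):
        if part in parts:
            xy = np.asarray(parts[part], float)
            if xy.ndim == 1:
                xy = np.tile(xy, (n_frames, 1))
        else:
            xy = np.tile([float(k), -10.0], (n_frames, 1))
        cols[(part, "x")] = xy[:, 0]
        cols[(part, "y")] = xy[:, 1]
        cols[(part, "likelihood")] = np.full(n_frames, likelihood)
    frame = pd.DataFrame(cols)
    frame.columns = pd.MultiIndex.from_tuples(frame.columns)
    return PoseTrack(frame, frame_rate)


@pytest.fixture
def kg_trial():
    """One Kármán-gait synthetic trial at default noise."""
    from finwake.synthetic_data import sample_trial_config, simulate_trial

    cfg = sample_trial_config("karman_gait", seed=11)
    track, rec, truth = simulate_trial(cfg)
    return cfg, track, rec, truth


@pytest.fixture
def braking_trial():
    from finwake.synthetic_data import sample_trial_config, simulate_trial

    cfg = sample_trial_config("braking", seed=7)
    track, rec, truth = simulate_trial(cfg)
    return cfg, track, rec, truth
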