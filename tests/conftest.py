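import numpy as np
import pandas as pd
import pytest

from affecteeg import synthgen as sg
from affecteeg import preprocess as pp
from affecteeg.recording import CHANNELS, EpochSet, Recording


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_session():
    """A small artifact-free session: 4 movies x ~24 s at 128 Hz."""
    cfg = sg.SynthConfig(
        fs=128.0, n_movies=4, neutral_s=4.0, seed=7,
        blink_rate=0.0, motion_rate=0.0, flatline_prob=0.0,
    )
    scen = sg.make_scenarios(4, seed=3, duration_range=(24.0, 25.0),
                             asym_effect=1.0)
    rec, truth = sg.generate_session(cfg, scen, subject=0)
    return cfg, scen, rec, truth


@pytest.fixture(scope="session")
def small_epochs(small_session):
    _, _, rec, _ = small_session
    return pp.build_epochset(pp.filter_recording(rec))


def zeros_recording(fs=128.0, seconds=60.0, n_movies=1):
    """Silent recording with evenly spaced movie markers, for artifact tests."""
    n = int(fs * seconds)
    per = n // n_movies
    markers = pd.DataFrame(
        [
            {"movie_id": f"M{i:03d}", "start": i * per, "stop": (i + 1) * per}
            for i in range(n_movies)
        ]
    )
    return Recording("S00", np.zeros((len(CHANNELS), n)), fs, CHANNELS, markers)
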