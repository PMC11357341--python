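import numpy as np
import pytest

from photolick.lickometer import LickRecord, LickSession
from photolick.synthetic import BoutModel, MotionParams, SimConfig


@pytest.fixture
def small_config() -> SimConfig:
    """A short, fully featured session that runs in well under a second."""
    return SimConfig(
        session_duration=900.0,
        bout_model=BoutModel(n_bouts=6),
        seed=123,
    )


@pytest.fixture
def quiet_config() -> SimConfig:
    """No drinks, no noise, no motion: the pure bleaching signal."""
    return SimConfig(
        session_duration=900.0,
        noise_sigma=0.0,
        motion=MotionParams(rate_per_min=0.0, amplitude=0.0, duration=1.0),
        bout_model=BoutModel(n_bouts=0),
        seed=5,
    )


def make_session(records, duration=7200.0, **kwargs) -> LickSession:
    defaults = dict(
        animal_id="T01",
        sex="male",
        fluid="water",
        session_index=1,
        week=1,
        duration=duration,
    )
    defaults.update(kwargs)
    return LickSession(records=[LickRecord(*r) for r in records], **defaults)


def random_lick_session(rng: np.random.Generator, duration: float = 3600.0) -> LickSession:
    """Random occupied-window pattern for oracle comparisons."""
    n_bins = int(duration // 3)
    occupied = np.sort(
        rng.choice(n_bins, size=rng.integers(0, min(60, n_bins)), replace=False)
    )
    records = [
        (float(b * 3.0), int(rng.integers(1, 30)), float(rng.uniform(0.0, 3.0)))
        for b in occupied
    ]
    return make_session(records, duration=duration)
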