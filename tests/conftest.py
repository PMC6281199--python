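import numpy as np
import pytest

from alphaloop import ChannelMap, EffectSpec, TrialSchedule, design_mfb
from alphaloop.prep import EpochSet
from alphaloop.synth import generate_session


@pytest.fixture(scope="session")
def alpha_spec():
    """The canonical alpha design: 12 Hz center, Q = 1.5 (8-16 Hz passband)."""
    return design_mfb(12.0, 1.5, A0_mag=1.0, C=100e-9)


@pytest.fixture(scope="session")
def small_map():
    return ChannelMap.grid(arrays=(1, 2)).subsample(4, seed=0)


@pytest.fixture(scope="session")
def small_session(small_map):
    """Two-condition synthetic session, 5 trials each, with a +1 dB alpha effect."""
    sched = TrialSchedule(
        rest_duration=12.0,
        trials_per_block=5,
        inter_block_rest=12.0,
        block_conditions=("closed", "open"),
    )
    return generate_session(
        [EffectSpec("closed", 1, "alpha", 1.0, duration=1.5)],
        sched,
        small_map,
        seed=11,
    )


def make_epochs(data, fs=1000.0, t0=-1.5, labels=None, cmap=None):
    """EpochSet from a bare (trials, channels, times) array."""
    data = np.asarray(data, dtype=np.float32)
    n_tr, _, n_t = data.shape
    return EpochSet(
        data=data,
        times=t0 + np.arange(n_t) / fs,
        fs=fs,
        labels=np.asarray(labels if labels is not None else ["closed"] * n_tr),
        trial_ids=np.arange(n_tr),
        channels=cmap if cmap is not None else ChannelMap.grid(arrays=(1,)).subsample(2),
        alignment="offset",
    )
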