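import numpy as np
import pytest

from bremtool.entropies import EntropyConfig
from bremtool.rhythms import EEGSignal
from bremtool.synthetic import SyntheticConfig, generate_subject


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def cfg():
    return EntropyConfig()


def make_sinusoid(freq, fs=128.0, seconds=5.0, phase=0.0):
    t = np.arange(int(seconds * fs)) / fs
    return np.sin(2 * np.pi * freq * t + phase)


@pytest.fixture
def noise_signal(rng):
    return EEGSignal(samples=rng.standard_normal(640), fs=128.0,
                     channel="O2", trial_id="t0")


@pytest.fixture
def alpha_signal():
    return EEGSignal(samples=make_sinusoid(10.0), fs=128.0, channel="O2",
                     trial_id="t1")


def small_subject(seed=0, effect=0.0, n_pos=4, n_neg=3, trial_s=5.0,
                  channels=("O2",), **kw):
    cfg = SyntheticConfig(seed=seed, effect=effect, n_pos=n_pos, n_neg=n_neg,
                          trial_s=trial_s, channels=channels,
                          signal_channel=kw.pop("signal_channel", channels[0]),
                          **kw)
    return generate_subject(cfg)


@pytest.fixture
def tiny_trialset():
    return small_subject(seed=5)
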