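import numpy as np
import pytest

from crossfatigue.eegsim import SynthConfig, make_domain_pair
from crossfatigue.types import EEGRecording, LabelSeries


@pytest.fixture(scope="session")
def small_pair():
    """A small shifted domain pair used by several structural tests."""
    cfg = SynthConfig(duration=24.0, n_recordings_per_domain=2, shift=1.0,
                      seed=11)
    return make_domain_pair(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def index_recording():
    """A 30 s, 4-channel recording with noise-free index-anchor labels."""
    fs = 128.0
    n = int(30 * fs)
    data = np.random.default_rng(7).normal(size=(4, n))
    labels = LabelSeries(np.arange(0.0, 30.0, 8.0), [0.1, 0.4, 0.8, 0.6],
                         span_start=0.0, span_end=30.0)
    return EEGRecording(data=data, fs=fs, channel_names=list("ABCD"),
                        domain="source", labels=labels, recording_id="fix-0")
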