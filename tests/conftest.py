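import numpy as np
import pytest

from kandetect.simulate import SimConfig, blink_train, gen_background, inject_blinks


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def blinked_recording():
    """A 60 s background recording with planted blinks and the blink train."""
    cfg = SimConfig(duration_s=60.0)
    clean = gen_background(cfg, seed=100)
    blinked = inject_blinks(clean, cfg, seed=200)
    train = blink_train(clean, cfg, seed=200)
    return clean, blinked, train
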