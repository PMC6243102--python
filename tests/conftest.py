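import numpy as np
import pytest

from improvlearn.melody import MelodyLine


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


def random_melody(rng, length, max_ioi_choices=(0.25, 1 / 3, 0.5, 2 / 3, 1.0, 1.5, 2.0)):
    """A random monophonic line on a metrical IOI grid."""
    iois = rng.choice(max_ioi_choices, size=length - 1)
    onsets = np.concatenate([[0.0], np.cumsum(iois)])
    pitches = 60 + np.cumsum(rng.integers(-4, 5, size=length))
    pitches = np.clip(pitches, 10, 117)
    return MelodyLine(
        "rand", tuple((float(o), int(p)) for o, p in zip(onsets, pitches))
    )


@pytest.fixture
def melody_factory(rng):
    def make(length=30):
        return random_melody(rng, length)

    return make
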