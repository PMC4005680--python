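import numpy as np
import pytest

from tfbench.pwm import PWM, BASES


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_pwm(rng, k):
    """A valid random PWM (not via gen_pwm, to stay independent of it)."""
    cols = rng.random((4, k)) + 0.05
    return PWM(cols / cols.sum(axis=0))


def random_seq(rng, length):
    return "".join(rng.choice(list(BASES), size=length))


@pytest.fixture
def pwm_factory(rng):
    return lambda k: random_pwm(rng, k)


@pytest.fixture
def seq_factory(rng):
    return lambda L: random_seq(rng, L)
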