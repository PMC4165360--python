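import numpy as np
import pytest

from zingerscan import motifs, simulate


@pytest.fixture
def rng():
    return np.random.default_rng(20140412)


@pytest.fixture(scope="session")
def zingers():
    return simulate.zinger_pfms()


@pytest.fixture(scope="session")
def jun_pwm(zingers):
    return motifs.pfm_to_pwm(zingers["JUN_like"])


def random_sequence(rng, length, gc=0.5):
    bases = np.array(list("ACGT"))
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(bases, size=length, p=p))
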