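import numpy as np
import pytest

from sh3kit.motif import AA_INDEX, PWM
from sh3kit.seqstruct import AA_ALPHABET


def one_hot_pwm(consensus: str, name: str = "onehot") -> PWM:
    """PWM with probability 1 on the consensus residue at each position."""
    f = np.zeros((len(consensus), len(AA_ALPHABET)))
    for i, aa in enumerate(consensus):
        f[i, AA_INDEX[aa]] = 1.0
    return PWM(name=name, f=f)


def random_pwm(rng: np.random.Generator, width: int, name: str = "rand") -> PWM:
    f = rng.dirichlet(np.ones(len(AA_ALPHABET)) * 0.5, size=width)
    return PWM(name=name, f=f)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
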