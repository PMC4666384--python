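import numpy as np
import pytest

from bindshift import Pwm, pwm_to_energy


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def sharp_pwm():
    """A 6-column PWM with an unambiguous ACGTAC consensus."""
    cols = []
    for base in "ACGTAC":
        idx = "ACGT".index(base)
        col = np.full(4, 0.02)
        col[idx] = 0.94
        cols.append(col)
    return Pwm(id="sharp", tf_name="SHARP", probs=np.array(cols).T)


@pytest.fixture
def sharp_energy(sharp_pwm):
    return pwm_to_energy(sharp_pwm)


@pytest.fixture
def uniform_pwm():
    return Pwm(id="flat", tf_name="FLAT", probs=np.full((4, 5), 0.25))


def random_sequence(rng, n, alphabet="ACGT"):
    return "".join(rng.choice(list(alphabet), size=n))


@pytest.fixture
def make_sequence():
    return random_sequence
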