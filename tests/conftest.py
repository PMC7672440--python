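import numpy as np
import pytest

from regcouple import synthdata
from regcouple.config import SimConfig


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SimConfig(
        n_tf=6,
        n_gene=80,
        n_sample=60,
        targets_per_tf=10,
        frac_coupled_pairs=0.3,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return synthdata.generate_all(small_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def random_pwm(rng: np.random.Generator, length: int, concentration: float = 0.5):
    """A random PWM with Dirichlet columns (shared test helper)."""
    from regcouple.pairs import MotifPWM

    probs = rng.dirichlet(np.full(4, concentration), size=length)
    return MotifPWM(tf_id="tfX", probs=probs)


def random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))
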