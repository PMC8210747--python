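import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from satcons.scenarios import DEFAULT_MONOMER

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def monomer() -> str:
    """The package's synthetic 52-nt ancestral monomer (65% A+T)."""
    return DEFAULT_MONOMER


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20210127)


def random_seq(rng: np.random.Generator, n: int, at: float = 0.5) -> str:
    bases = np.array(list("ACGT"))
    p = [at / 2, (1 - at) / 2, (1 - at) / 2, at / 2]
    return "".join(rng.choice(bases, size=n, p=p))
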