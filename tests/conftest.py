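import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from dadalite.error_model import TransitionMatrix
from dadalite.simulate import complement_symmetric_T

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_T() -> TransitionMatrix:
    """Complement-symmetric rates spanning 2e-4..2e-3, as a typical PCR model."""
    return complement_symmetric_T()


@pytest.fixture(scope="session")
def asym_T() -> TransitionMatrix:
    """A deliberately asymmetric matrix exercising all 12 distinct rates."""
    rng = np.random.default_rng(42)
    probs = np.zeros((4, 4))
    off = rng.uniform(2e-4, 3e-3, size=12)
    k = 0
    for i in range(4):
        for j in range(4):
            if i != j:
                probs[i, j] = off[k]
                k += 1
        probs[i, i] = 1.0 - probs[i].sum()
    return TransitionMatrix(probs)


def random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))
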