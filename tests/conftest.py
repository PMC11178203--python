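import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pstopt import StudyDesign

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def hypothetical_design():
    """Two-arm trial: 100 vs 70 participants, medium effect, prior odds 1, C=0.25."""
    return StudyDesign(n1=100, n2=70, d=0.5, pr=0.5, C=0.25)


@pytest.fixture
def rng():
    return np.random.default_rng(20240614)


def random_designs(rng, n):
    """Draw valid equal-variance study designs spanning the practical range."""
    designs = []
    for _ in range(n):
        n1 = int(rng.integers(5, 1000))
        n2 = int(rng.integers(5, 1000))
        d = float(rng.uniform(0.2, 1.2))
        pr = float(rng.uniform(0.05, 0.95))
        C = float(rng.uniform(0.05, 1.0))
        designs.append(StudyDesign(n1=n1, n2=n2, d=d, pr=pr, C=C))
    return designs
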