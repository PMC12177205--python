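import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=30)
settings.load_profile("ci")

ALL_FAMILIES = ["gaussian", "clayton", "gumbel", "frank", "fgm", "amh"]
ROTATIONS = ["clayton90", "clayton180", "clayton270"]


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def random_theta(name, rng, n=1):
    """Dependence parameters inside each family's admissible range, away
    from the boundary."""
    base = name.rstrip("0123456789")
    if base == "gaussian":
        return rng.uniform(-0.9, 0.9, n)
    if base == "clayton":
        return rng.uniform(0.2, 8.0, n)
    if base == "gumbel":
        return rng.uniform(1.05, 6.0, n)
    if base == "frank":
        return rng.uniform(-15.0, 15.0, n)
    if base == "fgm":
        return rng.uniform(-0.95, 0.95, n)
    if base == "amh":
        return rng.uniform(-0.9, 0.9, n)
    raise ValueError(name)
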