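import numpy as np
import pytest

from kleptodyn import Params, baseline


@pytest.fixture(scope="session")
def base() -> Params:
    return baseline()


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20240402)


def random_params(rng, n):
    """Positive parameter draws spanning the regimes exercised in the study."""
    out = []
    for _ in range(n):
        out.append(Params(
            A1=rng.uniform(0.01, 0.2), A2=rng.uniform(0.01, 0.2),
            A3=rng.uniform(0.1, 3.0), A4=rng.uniform(0.05, 2.0),
            A5=rng.uniform(0.5, 10.0), A6=rng.uniform(0.01, 0.2),
            A7=rng.uniform(0.5, 10.0), A8=rng.uniform(1.0, 150.0)))
    return out
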