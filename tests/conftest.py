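import numpy as np
import pytest

from trioscreen import NamedMatrix, SimConfig, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(20230917)


@pytest.fixture
def small_triple():
    """A clean 50-observation triple with one planted interaction."""
    cfg = SimConfig(n=50, p1=2, p2=3, p3=2, beta=(0.0, 0.3, 0.3, 0.8),
                    planted=[(0, 1, 0)], seed=11)
    return generate_dataset(cfg)


def random_named(rng, n, p, prefix):
    return NamedMatrix(
        rng.standard_normal((n, p)),
        [f"obs{i}" for i in range(n)],
        [f"{prefix}{j}" for j in range(p)],
    )
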