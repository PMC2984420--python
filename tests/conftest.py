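import numpy as np
import pytest

from mirstab.synthetic import (
    GroupSpec,
    SyntheticSpec,
    generate_population,
    table1_like_spec,
)


@pytest.fixture(scope="session")
def table1_population():
    """Three-species population with Table-1-like sizes and AMFE spreads."""
    return generate_population(table1_like_spec(seed=20260924))


@pytest.fixture(scope="session")
def small_population():
    """Single-species population with one planted cell per group."""
    spec = SyntheticSpec(
        populations={
            "synth": {
                "S_n": GroupSpec(n=50, group="S_n"),
                "S_c1": GroupSpec(n=15, group="S_c1"),
                "S_c2": GroupSpec(n=20, group="S_c2"),
                "S_c3": GroupSpec(n=20, group="S_c3"),
            }
        },
        seed=42,
    )
    return generate_population(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
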