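import pytest

from medconn.synthetic import LatticeSpec, generate_dataset


@pytest.fixture(scope="session")
def small_spec() -> LatticeSpec:
    """A 10x10 lattice with an 8-column dorsal-rim arc; study-default pitch,
    mosaic probability and slab thickness."""
    return LatticeSpec(n_rows=10, n_cols=10, n_dra=8, seed=42)


@pytest.fixture(scope="session")
def small_dataset(small_spec):
    return generate_dataset(small_spec)
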