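import numpy as np
import pytest

from xlmapdock.synthetic_data import ToySpec, make_toy_monomer, make_true_dimer


@pytest.fixture(scope="session")
def small_toy_spec():
    """A small, fast toy monomer spec shared across structural tests."""
    return ToySpec(n_helices=2, helix_length=12, seed=7,
                   lysine_positions=(4, 7, 15, 20))


@pytest.fixture(scope="session")
def small_toy(small_toy_spec):
    return make_toy_monomer(small_toy_spec)


@pytest.fixture(scope="session")
def small_monomer(small_toy):
    return small_toy[1]


@pytest.fixture(scope="session")
def small_dimer(small_monomer):
    """Planted translation dimer on the small toy (no packing search: fast)."""
    return make_true_dimer(
        small_monomer, orientation="parallel", direction=np.array([0.0, 1.0, 0.0]),
        optimize_packing=False,
    )
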