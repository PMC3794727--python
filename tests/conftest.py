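"""Shared fixtures: synthetic structures and engine tables."""

import numpy as np
import pytest

from gofold.engine import build_pair_tables
from gofold.synthetic import make_minifold


@pytest.fixture(scope="session")
def minifold():
    """Default (hairpin) minifold: cooperative two-state folder."""
    return make_minifold(12, seed=1)


@pytest.fixture(scope="session")
def minifold_tables(minifold):
    m = minifold.model
    return build_pair_tables(m.atoms, m.bonds, m.contacts)


@pytest.fixture(scope="session")
def helix_minifold():
    return make_minifold(10, seed=1, topology="helix")


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
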