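import numpy as np
import pytest

from m1alink.data_io import BinaryAssociationMatrix, EntityIndex, OntologyDAG, SequenceWindow
from m1alink.synthetic import SyntheticSpec, generate
from m1alink.training import build_dataset


def random_window(rng, site_id):
    seq = rng.choice(list("AUGC"), size=65)
    seq[32] = "A"
    return SequenceWindow(site_id=site_id, sequence="".join(seq))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def toy_dag():
    """Two sibling diseases under one parent."""
    return OntologyDAG(
        nodes=frozenset({"d1", "d2", "p"}),
        parents={"d1": frozenset({"p"}), "d2": frozenset({"p"})},
        decay=0.5,
    )


@pytest.fixture
def toy_assoc():
    rows = EntityIndex(("a", "b", "c"), kind="m1a_site")
    cols = EntityIndex(("x", "y", "z"), kind="disease")
    return BinaryAssociationMatrix(rows, cols, np.array([[1, 1, 0], [1, 0, 1], [0, 0, 0]]))


@pytest.fixture(scope="session")
def small_synthetic():
    """A small but learnable planted-block dataset for pipeline tests."""
    return generate(SyntheticSpec(n_m1a=40, n_circ=12, n_disease=9, n_blocks=3,
                                  p_in=0.9, p_out=0.05, noise=0.05, seed=7))


@pytest.fixture(scope="session")
def small_dataset(small_synthetic):
    d = small_synthetic
    return build_dataset(d.amc, d.acd, d.amd, d.windows, d.dag)
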