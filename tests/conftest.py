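import dendropy
import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from mitoarch.codon_model import CodonModel, PhyloTree
from mitoarch.datasets import load_reference_record


@pytest.fixture(scope="session")
def reference_record():
    """Coordinate-only record of the published MH119311 annotation."""
    return load_reference_record()


@pytest.fixture(scope="session")
def codon_model():
    return CodonModel()


@pytest.fixture(scope="session")
def uniform_pi(codon_model):
    return np.full(codon_model.n, 1.0 / codon_model.n)


@pytest.fixture()
def quartet_tree():
    """Littorinid-shaped 4-taxon tree (5 branches once derooted)."""
    t = dendropy.Tree.get(
        data="((A:0.2,B:0.3):0.1,(C:0.15,D:0.25):0.05);", schema="newick"
    )
    t.is_rooted = True
    return t


@pytest.fixture()
def quartet_ptree(quartet_tree):
    return PhyloTree(quartet_tree)
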