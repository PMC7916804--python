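import numpy as np
import pytest

import phyloabc as pa

#: Newick of the worked 3-taxon example tree: root D, D->C 250,
#: D->E 120, E->A and E->B each 130 (all tip depths 250).
THREE_TAXON_NEWICK = "(C:250,(A:130,B:130)E:120)D;"


@pytest.fixture
def three_taxon_tree():
    return pa.read_newick(THREE_TAXON_NEWICK)


@pytest.fixture
def two_tip_tree():
    return pa.read_newick("(A:1,B:1);")


@pytest.fixture(scope="session")
def balanced16():
    return pa.balanced_tree(16)


@pytest.fixture(scope="session")
def balanced64():
    return pa.balanced_tree(64)


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)
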