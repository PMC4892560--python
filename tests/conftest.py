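import pytest

import pieces


@pytest.fixture()
def balanced4():
    """4-tip balanced ultrametric tree: ((A:1,B:1):1,(C:1,D:1):1)."""
    return pieces.read_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture(scope="session")
def yule128():
    return pieces.yule_tree(128, seed=42)


@pytest.fixture(scope="session")
def fixture500():
    """Paper-shaped synthetic fixture: (tree, table, raw ED)."""
    tree, table = pieces.paper_shaped_fixture(seed=1)
    ed = pieces.fair_proportion(tree)
    return tree, table, ed
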