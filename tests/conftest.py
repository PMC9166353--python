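import numpy as np
import pytest

from pcmkit import parse_newick, simulate_yule


@pytest.fixture
def three_tip_tree():
    """((A:1,B:1):1,C:2); — the standard worked example."""
    return parse_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def balanced_six_tree():
    return parse_newick(
        "(((A:0.4,B:0.6):0.5,(C:0.7,D:0.3):0.2):0.3,(E:0.9,F:1.1):0.4);"
    )


@pytest.fixture
def star_tree_newick():
    def make(n, height=1.0):
        tips = ",".join(f"s{i}:{height}" for i in range(n))
        return parse_newick(f"({tips});")

    return make


@pytest.fixture
def yule_tree():
    return simulate_yule(40, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
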