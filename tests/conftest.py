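import numpy as np
import pytest

from primdiv import AreaSystem, parse_newick


@pytest.fixture
def areas4():
    """The four-area system of the extant-primate reconstruction."""
    return AreaSystem(("Africa", "Madagascar", "Asia", "NewWorld"), max_range_size=2)


@pytest.fixture
def three_tip_tree():
    return parse_newick("((A:1,B:1):1,C:2):0;")


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


def random_topology_newick(rng, n_tips, depth_scale=1.0):
    """Random binary ultrametric tree via sequential coalescence of tips."""
    nodes = [(f"t{i}", 0.0) for i in range(n_tips)]
    age = 0.0
    while len(nodes) > 1:
        age += rng.exponential(depth_scale)
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        (s2, a2) = nodes.pop(j)
        (s1, a1) = nodes.pop(i)
        nodes.append((f"({s1}:{age - a1!r},{s2}:{age - a2!r})", age))
    return nodes[0][0] + ";"
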