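import numpy as np
import pytest

from phylopaint import SynthSpec, gen_tree
from phylopaint.newick_io import Node, iter_preorder


def random_tree(seed: int, max_leaves: int = 200, n_variables: int = 3):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, max_leaves + 1))
    return gen_tree(SynthSpec(n_leaves=n, n_variables=n_variables,
                              seed=seed))


def trees_equal(a: Node, b: Node) -> bool:
    """Structural equality: topology, names, lengths, inner labels."""
    stack = [(a, b)]
    while stack:
        x, y = stack.pop()
        if (x.name != y.name or x.inner_label != y.inner_label
                or len(x.children) != len(y.children)):
            return False
        if (x.branch_length is None) != (y.branch_length is None):
            return False
        if x.branch_length is not None and not np.isclose(
                x.branch_length, y.branch_length, rtol=0, atol=0):
            return False
        stack.extend(zip(x.children, y.children))
    return True


def leaf_list(root: Node) -> list[Node]:
    return [n for n in iter_preorder(root) if not n.children]


@pytest.fixture
def small_tree():
    from phylopaint import parse_newick
    return parse_newick("((A:1,B:2)90:0.5,C:3);")
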