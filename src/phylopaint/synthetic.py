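"""Deterministic generators for random trees, count tables and mapping files.

These drive the test suite and the large-scale stress runs.  Topology is
grown by sequential random attachment — each new leaf splits a uniformly
chosen existing edge — giving a bifurcating rooted tree; branch lengths are
i.i.d. uniform(0, 1), the same law used for million-leaf stress trees
produced with ``ape::rtree(runif)``.  All generators are pure functions of
their :class:`SynthSpec` (same spec, same output, bit for bit).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gradient import CountTable
from .newick_io import Node, Tree, iter_preorder

__all__ = ["SynthSpec", "SyntheticMapping", "gen_tree", "gen_counts",
           "gen_mapping"]


@dataclass(frozen=True)
class SynthSpec:
    """Parameters for one synthetic data set.

    ``n_leaves`` >= 2 leaves named t1..tn; ``n_variables`` columns in the
    count table; everything derives deterministically from ``seed``.
    ``poisson_mean`` is the expected count per cell.
    """

    n_leaves: int
    n_variables: int = 3
    seed: int = 0
    poisson_mean: float = 10.0

    def __post_init__(self) -> None:
        if self.n_leaves < 2:
            raise ValueError("n_leaves must be >= 2")
        if self.n_variables < 1:
            raise ValueError("n_variables must be >= 1")


def _rng(spec: SynthSpec, stream: int) -> np.random.Generator:
    # independent substreams per generator so outputs stay stable if one
    # generator is skipped
    return np.random.default_rng([spec.seed & 0x7FFFFFFF, stream])


def gen_tree(spec: SynthSpec) -> Tree:
    """Random bifurcating rooted tree via sequential random attachment.

    Each new leaf splits a uniformly chosen existing edge (an edge being any
    non-root node).  Generation is fully iterative, so million-leaf trees
    build without recursion-depth limits.  Branch lengths are uniform(0, 1)
    on every non-root node.
    """
    rng = _rng(spec, 1)
    n = spec.n_leaves
    root = Node()
    first, second = Node("t1"), Node("t2")
    root.children = [first, second]
    # attachable edges = non-root nodes; parent map kept alongside
    edges: list[Node] = [first, second]
    parent: dict[int, Node] = {id(first): root, id(second): root}
    # draw all edge picks up front for speed
    if n > 2:
        picks = rng.integers(0, 2 + 2 * np.arange(n - 2), dtype=np.int64)
    else:
        picks = np.empty(0, dtype=np.int64)
    for i in range(n - 2):
        target = edges[int(picks[i])]
        par = parent[id(target)]
        mid = Node()
        leaf = Node(f"t{i + 3}")
        mid.children = [target, leaf]
        par.children[par.children.index(target)] = mid
        parent[id(target)] = mid
        parent[id(mid)] = par
        parent[id(leaf)] = mid
        edges.append(mid)
        edges.append(leaf)
    # assign branch lengths in pre-order so output is seed-deterministic
    lengths = rng.uniform(0.0, 1.0, size=2 * n - 2)
    k = 0
    for node in iter_preorder(root):
        if node is root:
            continue
        node.branch_length = float(lengths[k])
        k += 1
    return Tree(root)


def gen_counts(spec: SynthSpec, tree: Tree) -> CountTable:
    """Poisson count table with one row per leaf name.

    Rows are redrawn until they contain at least one strictly positive
    entry, so evenness is defined for every observation.
    """
    rng = _rng(spec, 2)
    names = [leaf.name for leaf in tree.leaves()]
    m, n = len(names), spec.n_variables
    counts = rng.poisson(spec.poisson_mean, size=(m, n)).astype(np.float64)
    while True:
        dead = np.nonzero(counts.sum(axis=1) == 0)[0]
        if dead.size == 0:
            break
        counts[dead] = rng.poisson(spec.poisson_mean,
                                   size=(dead.size, n)).astype(np.float64)
    return CountTable(names, [f"v{j + 1}" for j in range(n)], counts)


@dataclass
class SyntheticMapping:
    """A generated mapping file plus its planted uniform clade.

    ``clade_root`` subtends exactly the leaves that all received
    ``clade_color``, so style propagation has a known positive case.
    """

    tsv: str
    clade_root: Node
    clade_color: str


def gen_mapping(spec: SynthSpec, tree: Tree,
                n_colors: int = 5) -> SyntheticMapping:
    """Assign each leaf a random branch color, with one contiguous clade
    forced to a single uniform color."""
    rng = _rng(spec, 3)
    palette = ["#%06X" % int(v) for v in
               rng.integers(0, 0x1000000, size=n_colors)]
    leaves = tree.leaves()
    leaf_set = set(map(id, leaves))
    # candidate planted clades: proper inner nodes (not the root when
    # possible) with at least 2 leaves
    inner = [nd for nd in iter_preorder(tree.root)
             if nd.children and nd is not tree.root]
    clade = inner[int(rng.integers(0, len(inner)))] if inner else tree.root
    clade_leaves = {id(nd) for nd in iter_preorder(clade)
                    if id(nd) in leaf_set}
    clade_color = palette[0]
    rest = palette[1:] or palette
    choice = rng.integers(0, len(rest), size=len(leaves))
    lines = ["name\tbranch_color"]
    for i, leaf in enumerate(leaves):
        color = clade_color if id(leaf) in clade_leaves \
            else rest[int(choice[i])]
        lines.append(f"{leaf.name}\t{color}")
    return SyntheticMapping("\n".join(lines) + "\n", clade, clade_color)
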