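"""Per-node coordinates for rectangular, circular and radial tree layouts.

All traversals are iterative so that million-leaf trees lay out without
recursion-depth failures.  Coordinates are abstract units; the renderer
scales them onto the canvas.

Conventions
-----------
* Rectangular: x = longitudinal (cumulative branch length from the root, or
  hop depth in cladogram mode), y = transverse (leaf index).  Leaves get
  transverse 0, 1, 2, ... in depth-first child order; an inner node sits at
  the midpoint of its first and last child (the cluster-dendrogram rule), or
  optionally at the mean of all children.
* Circular: the rectangular transverse axis maps linearly onto angle —
  leaf k of n gets angle k*sweep/n — and the longitudinal axis onto radius.
  Angles are radians, 0 along +x, counterclockwise.
* Radial: the equal-wedge algorithm — the root owns the full circle and, in
  pre-order, each child is allocated a consecutive sub-wedge of angular
  width proportional to its leaf count; the child is placed one branch
  length from its parent along the wedge's bisector.
"""

from __future__ import annotations

import logging
import math
from typing import Optional

from .newick_io import Node, Tree, iter_postorder, iter_preorder

logger = logging.getLogger(__name__)

__all__ = [
    "Placement",
    "LayoutResult",
    "count_leaves",
    "layout_rectangular",
    "layout_circular",
    "layout_radial",
]


class Placement:
    """Layout coordinates for one node.

    ``angle``/``radius`` are set by the circular and radial layouts only;
    ``wedge_start``/``wedge_width`` by the radial layout only. ``depth`` is
    the cumulative branch length (or hop count) from the root.
    """

    __slots__ = ("node", "x", "y", "angle", "radius", "depth",
                 "wedge_start", "wedge_width")

    def __init__(self, node: Node, x: float, y: float,
                 angle: Optional[float] = None,
                 radius: Optional[float] = None,
                 depth: float = 0.0,
                 wedge_start: Optional[float] = None,
                 wedge_width: Optional[float] = None) -> None:
        self.node = node
        self.x = x
        self.y = y
        self.angle = angle
        self.radius = radius
        self.depth = depth
        self.wedge_start = wedge_start
        self.wedge_width = wedge_width


class LayoutResult:
    """All placements for one layout run, keyed by node identity."""

    __slots__ = ("mode", "placements", "by_node", "width", "height")

    def __init__(self, mode: str, placements: list[Placement]) -> None:
        self.mode = mode
        self.placements = placements
        self.by_node: dict[Node, Placement] = {p.node: p for p in placements}
        xs = [p.x for p in placements]
        ys = [p.y for p in placements]
        self.width = max(xs) - min(xs) if xs else 0.0
        self.height = max(ys) - min(ys) if ys else 0.0

    def __getitem__(self, node: Node) -> Placement:
        return self.by_node[node]


def count_leaves(node: Node) -> int:
    """Number of leaf descendants of ``node`` (a leaf counts itself)."""
    return _leaf_counts(node)[node]


def _leaf_counts(root: Node) -> dict[Node, int]:
    counts: dict[Node, int] = {}
    for node in iter_postorder(root):
        counts[node] = 1 if node.is_leaf else sum(
            counts[c] for c in node.children)
    return counts


def _depths(tree: Tree, use_branch_lengths: bool) -> tuple[dict[Node, float], bool]:
    """Cumulative depth per node; returns (depths, used_lengths)."""
    used = use_branch_lengths and tree.has_lengths
    if use_branch_lengths and not tree.has_lengths:
        logger.warning(
            "tree lacks branch lengths; falling back to cladogram layout")
    depths: dict[Node, float] = {tree.root: 0.0}
    stack = [tree.root]
    while stack:
        node = stack.pop()
        d = depths[node]
        for child in node.children:
            step = (child.branch_length or 0.0) if used else 1.0
            depths[child] = d + step
            stack.append(child)
    return depths, used


def layout_rectangular(tree: Tree, use_branch_lengths: bool = True,
                       inner_rule: str = "midpoint") -> LayoutResult:
    """Rectangular (dendrogram) layout.

    Phylogram when ``use_branch_lengths`` and the tree has lengths;
    otherwise cladogram: every leaf at the maximum hop depth, inner nodes at
    their own hop depth.  ``inner_rule`` places inner nodes at the
    ``"midpoint"`` of their extreme children (default) or the ``"mean"`` of
    all children.
    """
    if inner_rule not in ("midpoint", "mean"):
        raise ValueError(f"unknown inner_rule {inner_rule!r}")
    depths, used = _depths(tree, use_branch_lengths)
    if not used:
        max_depth = max(depths.values())
        for node in depths:
            if node.is_leaf:
                depths[node] = max_depth
    trans: dict[Node, float] = {}
    next_leaf = 0
    # Leaf indices follow depth-first (pre-order) child order.
    for node in iter_preorder(tree.root):
        if node.is_leaf:
            trans[node] = float(next_leaf)
            next_leaf += 1
    for node in iter_postorder(tree.root):
        if not node.is_leaf:
            if inner_rule == "midpoint":
                trans[node] = (trans[node.children[0]]
                               + trans[node.children[-1]]) / 2.0
            else:
                trans[node] = sum(trans[c] for c in node.children) / len(
                    node.children)
    placements = [
        Placement(n, x=depths[n], y=trans[n], depth=depths[n])
        for n in iter_preorder(tree.root)
    ]
    return LayoutResult("rectangular", placements)


def layout_circular(tree: Tree, sweep_degrees: float = 360.0,
                    use_branch_lengths: bool = True,
                    inner_rule: str = "midpoint") -> LayoutResult:
    """Circular layout: polar transform of the rectangular layout.

    Leaf k of n gets angle k*sweep/n; radius equals the rectangular
    longitudinal coordinate.  ``sweep_degrees`` must lie in (0, 360]; a
    sweep below 360 leaves a gap for label readability.
    """
    if not (0.0 < sweep_degrees <= 360.0):
        raise ValueError(
            f"sweep_degrees must be in (0, 360], got {sweep_degrees}")
    rect = layout_rectangular(tree, use_branch_lengths, inner_rule)
    sweep = math.radians(sweep_degrees)
    n = tree.n_leaves
    placements = []
    for p in rect.placements:
        angle = p.y * sweep / n
        radius = p.x
        placements.append(Placement(
            p.node,
            x=radius * math.cos(angle),
            y=radius * math.sin(angle),
            angle=angle, radius=radius, depth=p.depth,
        ))
    return LayoutResult("circular", placements)


def layout_radial(tree: Tree) -> LayoutResult:
    """Equal-wedge radial layout.

    The root sits at the origin owning the wedge [0, 2*pi); each child of a
    node v is allocated a consecutive sub-wedge of width
    2*pi * leaves(child) / leaves(root) starting at v's wedge start, and is
    placed at v's position plus its branch length along the wedge bisector.
    Trees without branch lengths use unit lengths (with a warning).
    """
    if not tree.has_lengths:
        logger.warning(
            "tree lacks branch lengths; radial layout uses unit lengths")
    counts = _leaf_counts(tree.root)
    total = counts[tree.root]
    two_pi = 2.0 * math.pi
    root = tree.root
    place: dict[Node, Placement] = {
        root: Placement(root, 0.0, 0.0, angle=0.0, radius=0.0, depth=0.0,
                        wedge_start=0.0, wedge_width=two_pi)
    }
    order = [root]
    stack = [root]
    while stack:
        v = stack.pop()
        pv = place[v]
        eta = pv.wedge_start
        for w in v.children:
            width = two_pi * counts[w] / total
            tau = eta + width / 2.0
            bl = w.branch_length if w.branch_length is not None else 1.0
            if not tree.has_lengths:
                bl = 1.0
            pw = Placement(
                w,
                x=pv.x + bl * math.cos(tau),
                y=pv.y + bl * math.sin(tau),
                angle=tau,
                radius=None,
                depth=pv.depth + bl,
                wedge_start=eta,
                wedge_width=width,
            )
            pw.radius = math.hypot(pw.x, pw.y)
            place[w] = pw
            eta += width
            stack.append(w)
            order.append(w)
    return LayoutResult("radial", [place[n] for n in order])
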