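"""Newick parsing and serialization for the rooted-tree model.

The parser is a hand-written iterative tokenizer/builder so that trees with
millions of leaves parse without hitting Python's recursion limit.  Dialect:

* single-quoted labels with ``''`` as the escape for a literal quote;
* underscores are **not** converted to spaces;
* bracketed comments ``[...]`` are discarded;
* the token after ``)`` and before ``:`` is the inner-node label (support
  value or free-text comment) — leaves never carry one;
* branch lengths are finite, non-negative reals after ``:``.

Multifurcations and single-child nodes are accepted as-is; no rerooting or
binarization is performed.
"""

from __future__ import annotations

import logging
import math
import re
from collections import Counter
from typing import Iterator, Optional

logger = logging.getLogger(__name__)

__all__ = ["Node", "Tree", "NewickParseError", "parse_newick", "write_newick"]


class NewickParseError(ValueError):
    """Malformed Newick input; ``offset`` is the 0-based character position."""

    def __init__(self, message: str, offset: int) -> None:
        super().__init__(f"{message} (at character {offset})")
        self.offset = offset


class Node:
    """A node of a rooted tree.

    A node is a leaf iff ``children`` is empty.  Child order is preserved
    exactly as parsed — layouts depend on it.  ``inner_label`` holds the
    token after a closing parenthesis (typically a support value); leaves
    never carry one.
    """

    __slots__ = ("name", "branch_length", "inner_label", "children")

    def __init__(
        self,
        name: str = "",
        branch_length: Optional[float] = None,
        inner_label: Optional[str] = None,
        children: Optional[list["Node"]] = None,
    ) -> None:
        self.name = name
        self.branch_length = branch_length
        self.inner_label = inner_label
        self.children: list[Node] = children if children is not None else []

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "Leaf" if self.is_leaf else f"Inner[{len(self.children)}]"
        return f"<{kind} {self.name!r} bl={self.branch_length}>"


class Tree:
    """A rooted tree: the root node plus cached whole-tree facts.

    ``has_lengths`` is true iff every non-root node carries a branch length;
    when false, layouts fall back to cladogram / unit-length modes.
    Duplicate leaf names are allowed but logged as a warning.
    """

    __slots__ = ("root", "n_leaves", "has_lengths")

    def __init__(self, root: Node) -> None:
        self.root = root
        n_leaves = 0
        has_lengths = True
        names: Counter[str] = Counter()
        for node in iter_preorder(root):
            if node.is_leaf:
                n_leaves += 1
                names[node.name] += 1
            if node is not root and node.branch_length is None:
                has_lengths = False
        self.n_leaves = n_leaves
        self.has_lengths = has_lengths
        dupes = [n for n, c in names.items() if c > 1]
        if dupes:
            logger.warning(
                "tree contains %d duplicated leaf name(s), e.g. %r",
                len(dupes), dupes[0],
            )

    def leaves(self) -> list[Node]:
        """Leaves in depth-first (rendering) order."""
        return [n for n in iter_preorder(self.root) if n.is_leaf]


def iter_preorder(root: Node) -> Iterator[Node]:
    """Depth-first pre-order traversal, iterative (stack-safe)."""
    stack = [root]
    while stack:
        node = stack.pop()
        yield node
        stack.extend(reversed(node.children))


def iter_postorder(root: Node) -> Iterator[Node]:
    """Depth-first post-order traversal, iterative (stack-safe)."""
    stack: list[tuple[Node, bool]] = [(root, False)]
    while stack:
        node, expanded = stack.pop()
        if expanded or node.is_leaf:
            yield node
        else:
            stack.append((node, True))
            stack.extend((c, False) for c in reversed(node.children))


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

# One token per alternative: structural chars, quoted label, bare label.
_TOKEN_RE = re.compile(
    r"""
    \s+                    # whitespace (skipped)
  | \[[^\]]*\]             # bracketed comment (discarded)
  | '(?:[^']|'')*'         # quoted label, '' escapes a quote
  | [(),:;]                # structure
  | [^()\[\],:;'\s]+       # bare label / number
    """,
    re.VERBOSE,
)


def _tokens(text: str) -> Iterator[tuple[str, int]]:
    pos = 0
    n = len(text)
    while pos < n:
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            raise NewickParseError(f"unexpected character {text[pos]!r}", pos)
        tok = m.group(0)
        if not tok[0].isspace() and tok[0] != "[":
            yield tok, pos
        pos = m.end()
        if tok[0] == "[" and not tok.endswith("]"):  # unreachable via regex
            raise NewickParseError("unterminated comment", pos)


def _unquote(tok: str) -> str:
    return tok[1:-1].replace("''", "'")


def parse_newick(text: str) -> Tree:
    """Parse a single ``;``-terminated Newick statement into a :class:`Tree`.

    Raises :class:`NewickParseError` (with character offset) on unbalanced
    parentheses, a missing terminator, empty input, or a non-numeric branch
    length.
    """
    root = Node()
    cur = root
    stack: list[Node] = []
    expect_length = False
    saw_semicolon = False
    last_pos = 0
    for tok, pos in _tokens(text):
        last_pos = pos
        if saw_semicolon:
            raise NewickParseError("content after ';'", pos)
        if expect_length:
            try:
                bl = float(tok)
            except ValueError:
                raise NewickParseError(
                    f"non-numeric branch length {tok!r}", pos
                ) from None
            if not math.isfinite(bl) or bl < 0:
                raise NewickParseError(
                    f"branch length must be finite and >= 0, got {tok}", pos
                )
            cur.branch_length = bl
            expect_length = False
            continue
        if tok == "(":
            stack.append(cur)
            child = Node()
            cur.children.append(child)
            cur = child
        elif tok == ",":
            if not stack:
                raise NewickParseError("',' outside parentheses", pos)
            parent = stack[-1]
            cur = Node()
            parent.children.append(cur)
        elif tok == ")":
            if not stack:
                raise NewickParseError("unbalanced ')'", pos)
            cur = stack.pop()
        elif tok == ":":
            expect_length = True
        elif tok == ";":
            saw_semicolon = True
        else:
            label = _unquote(tok) if tok.startswith("'") else tok
            if cur.children:
                if cur.inner_label is not None:
                    raise NewickParseError("duplicate inner label", pos)
                cur.inner_label = label
            else:
                if cur.name:
                    raise NewickParseError("duplicate leaf label", pos)
                cur.name = label
    if expect_length:
        raise NewickParseError("missing branch length after ':'", last_pos)
    if stack:
        raise NewickParseError("unbalanced '(': missing ')'", last_pos)
    if not saw_semicolon:
        raise NewickParseError("missing ';' terminator", last_pos)
    if root.is_leaf and not root.name and root.branch_length is None:
        raise NewickParseError("empty tree", 0)
    return Tree(root)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

_NEEDS_QUOTING = re.compile(r"[\s()\[\]':;,]")


def _format_label(label: str) -> str:
    if label == "" or _NEEDS_QUOTING.search(label):
        return "'" + label.replace("'", "''") + "'"
    return label


def _format_length(bl: Optional[float]) -> str:
    if bl is None:
        return ""
    text = repr(bl)
    return f":{text}"


def write_newick(tree: Tree) -> str:
    """Serialize a :class:`Tree` back to Newick.

    Labels containing Newick metacharacters or whitespace are single-quoted
    (with ``''`` escapes); the output re-parses to an equivalent tree.
    Iterative, so arbitrarily deep trees serialize safely.
    """
    out: list[str] = []
    # Stack entries are either literal strings or nodes still to expand.
    stack: list[object] = [tree.root]
    while stack:
        item = stack.pop()
        if isinstance(item, str):
            out.append(item)
            continue
        node: Node = item  # type: ignore[assignment]
        if node.is_leaf:
            out.append(
                (_format_label(node.name) if node.name else "")
                + _format_length(node.branch_length)
            )
            continue
        out.append("(")
        tail = ")"
        if node.inner_label is not None:
            tail += _format_label(node.inner_label)
        tail += _format_length(node.branch_length)
        stack.append(tail)
        for i, child in enumerate(reversed(node.children)):
            stack.append(child)
            if i != len(node.children) - 1:
                stack.append(",")
    out.append(";")
    return "".join(out)
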