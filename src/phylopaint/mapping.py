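"""Mapping files: leaf-name patterns plus style directives.

A mapping file is UTF-8 TSV with a required header whose first column is
``name``.  Each data row is one rule: the first cell is a pattern matched
against leaf labels (exact or substring, case-sensitive by default) and the
remaining cells are style directives.  Recognized style columns:

``branch_color``, ``branch_width``, ``label_color``, ``label_font_size``,
``new_name``, ``leaf_dot_color``, ``leaf_dot_size``, ``bar{k}_height``,
``bar{k}_color`` (k = 1, 2, 3, ...), ``arc_color``.

Empty cells mean "unspecified".  When several rules match one leaf they are
applied in file order, later rules overriding earlier ones field by field.
Inner nodes inherit a style value iff every descendant leaf agrees on it,
which makes uniformly-styled clades visually contiguous.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from typing import Optional

from .newick_io import Node, Tree, iter_postorder

logger = logging.getLogger(__name__)

__all__ = [
    "StyleSet",
    "MappingRule",
    "ResolvedStyles",
    "MatchReport",
    "MappingParseError",
    "parse_mapping",
    "normalize_hex",
    "resolve_leaf_styles",
    "propagate_styles",
    "support_decorations",
]


class MappingParseError(ValueError):
    """Malformed mapping file; carries 1-based row and column when known."""

    def __init__(self, message: str, row: Optional[int] = None,
                 col: Optional[int] = None) -> None:
        loc = ""
        if row is not None:
            loc = f" (row {row}" + (f", column {col})" if col else ")")
        super().__init__(message + loc)
        self.row = row
        self.col = col


_HEX_RE = re.compile(r"\A#(?:[0-9a-fA-F]{3}|[0-9a-fA-F]{6})\Z")


def normalize_hex(value: str) -> str:
    """Validate a hex color, expanding ``#abc`` to ``#AABBCC`` (uppercase)."""
    if not _HEX_RE.match(value):
        raise ValueError(f"not a hex color: {value!r}")
    digits = value[1:]
    if len(digits) == 3:
        digits = "".join(c * 2 for c in digits)
    return "#" + digits.upper()


@dataclass(frozen=True)
class StyleSet:
    """Style directives for one node; ``None`` means unspecified.

    ``bar_values`` is an ordered tuple of (height, color-or-None) pairs, one
    per bar series.
    """

    branch_color: Optional[str] = None
    branch_width: Optional[float] = None
    label_color: Optional[str] = None
    label_font_size: Optional[float] = None
    new_name: Optional[str] = None
    leaf_dot_color: Optional[str] = None
    leaf_dot_size: Optional[float] = None
    bar_values: tuple[tuple[float, Optional[str]], ...] = ()
    arc_color: Optional[str] = None

    def merged_over(self, base: "StyleSet") -> "StyleSet":
        """Field-by-field override: this set's specified fields win."""
        updates = {}
        for f in _SCALAR_FIELDS:
            v = getattr(self, f)
            if v is not None:
                updates[f] = v
        if self.bar_values:
            updates["bar_values"] = self.bar_values
        return replace(base, **updates)


_SCALAR_FIELDS = ("branch_color", "branch_width", "label_color",
                  "label_font_size", "new_name", "leaf_dot_color",
                  "leaf_dot_size", "arc_color")
_ALL_FIELDS = _SCALAR_FIELDS + ("bar_values",)

_COLOR_COLUMNS = {"branch_color", "label_color", "leaf_dot_color",
                  "arc_color"}
_NUMERIC_COLUMNS = {"branch_width", "label_font_size", "leaf_dot_size"}
_TEXT_COLUMNS = {"new_name"}
_BAR_RE = re.compile(r"\Abar([1-9][0-9]*)_(height|color)\Z")

DEFAULT_STYLE = StyleSet()


@dataclass(frozen=True)
class MappingRule:
    """One mapping-file row: a verbatim pattern plus its styles."""

    pattern: str
    styles: StyleSet


@dataclass
class MatchReport:
    """Bookkeeping from rule matching, reported to the user after a run."""

    unmatched_leaves: list[str] = field(default_factory=list)
    unused_rules: list[str] = field(default_factory=list)
    n_matched_leaves: int = 0


class ResolvedStyles:
    """Effective :class:`StyleSet` per node, against a shared default."""

    __slots__ = ("styles", "default")

    def __init__(self, styles: dict[Node, StyleSet],
                 default: StyleSet = DEFAULT_STYLE) -> None:
        self.styles = styles
        self.default = default

    def effective(self, node: Node) -> StyleSet:
        return self.styles.get(node, self.default)

    def is_default(self, node: Node) -> bool:
        return self.effective(node) == self.default


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

def _parse_number(raw: str, row: int, col: int, header: str) -> float:
    try:
        return float(raw)
    except ValueError:
        raise MappingParseError(
            f"non-numeric value {raw!r} in column {header!r}", row, col
        ) from None


def _parse_color(raw: str, row: int, col: int, header: str) -> str:
    try:
        return normalize_hex(raw)
    except ValueError:
        raise MappingParseError(
            f"invalid hex color {raw!r} in column {header!r}", row, col
        ) from None


def parse_mapping(text: str) -> list[MappingRule]:
    """Parse mapping-file TSV into rules.

    The header row is required; its first column must be ``name``.
    Unrecognized style headers are logged and ignored; duplicate headers,
    empty patterns, bad numbers and bad colors raise
    :class:`MappingParseError` with the offending row/column.
    """
    lines = text.split("\n")
    if lines and lines[-1] == "":
        lines.pop()
    lines = [ln[:-1] if ln.endswith("\r") else ln for ln in lines]
    if not lines:
        raise MappingParseError("empty mapping file: missing header", row=1)
    header = lines[0].split("\t")
    if header[0] != "name":
        raise MappingParseError(
            f"first header column must be 'name', got {header[0]!r}",
            row=1, col=1)
    seen: set[str] = set()
    # column index -> ("scalar"/"text"/"bar", target)
    columns: dict[int, tuple[str, object]] = {}
    for idx, h in enumerate(header[1:], start=2):
        if h in seen:
            raise MappingParseError(f"duplicate style header {h!r}",
                                    row=1, col=idx)
        seen.add(h)
        m = _BAR_RE.match(h)
        if m:
            columns[idx] = ("bar", (int(m.group(1)), m.group(2)))
        elif h in _COLOR_COLUMNS or h in _NUMERIC_COLUMNS or h in _TEXT_COLUMNS:
            columns[idx] = ("scalar", h)
        else:
            logger.warning("ignoring unrecognized mapping column %r", h)
    rules: list[MappingRule] = []
    for row_no, line in enumerate(lines[1:], start=2):
        cells = line.split("\t")
        if len(cells) > len(header):
            raise MappingParseError(
                f"row has {len(cells)} cells but header has {len(header)}",
                row=row_no)
        pattern = cells[0]
        if pattern == "":
            raise MappingParseError("empty pattern", row=row_no, col=1)
        updates: dict[str, object] = {}
        bars: dict[int, dict[str, object]] = {}
        for idx, cell in enumerate(cells[1:], start=2):
            if cell == "" or idx not in columns:
                continue
            kind, target = columns[idx]
            if kind == "bar":
                k, part = target  # type: ignore[misc]
                slot = bars.setdefault(k, {})
                if part == "height":
                    slot["height"] = _parse_number(
                        cell, row_no, idx, header[idx - 1])
                else:
                    slot["color"] = _parse_color(
                        cell, row_no, idx, header[idx - 1])
            else:
                h = target  # type: ignore[assignment]
                if h in _NUMERIC_COLUMNS:
                    updates[h] = _parse_number(cell, row_no, idx, h)
                elif h in _COLOR_COLUMNS:
                    updates[h] = _parse_color(cell, row_no, idx, h)
                else:
                    updates[h] = cell
        if bars:
            series = []
            for k in sorted(bars):
                slot = bars[k]
                if "height" not in slot:
                    logger.warning(
                        "row %d: bar%d_color given without bar%d_height; "
                        "ignored", row_no, k, k)
                    continue
                series.append((slot["height"], slot.get("color")))
            if series:
                updates["bar_values"] = tuple(series)
        rules.append(MappingRule(pattern, StyleSet(**updates)))  # type: ignore[arg-type]
    return rules


# ---------------------------------------------------------------------------
# Matching & propagation
# ---------------------------------------------------------------------------

def resolve_leaf_styles(
    tree: Tree,
    rules: list[MappingRule],
    mode: str = "exact",
    case_insensitive: bool = False,
    default: StyleSet = DEFAULT_STYLE,
) -> tuple[ResolvedStyles, MatchReport]:
    """Match rules to leaves and merge styles.

    ``mode`` is ``"exact"`` (pattern equals the leaf name) or
    ``"substring"`` (pattern occurs anywhere in it).  Rules apply in file
    order; later rules override earlier ones field by field.  Leaves matched
    by no rule keep ``default``.  Duplicate leaf names are each styled
    independently.
    """
    if mode not in ("exact", "substring"):
        raise ValueError(f"unknown match mode {mode!r}")
    styles: dict[Node, StyleSet] = {}
    report = MatchReport()
    used = [False] * len(rules)
    fold = (lambda s: s.lower()) if case_insensitive else (lambda s: s)
    patterns = [fold(r.pattern) for r in rules]
    for leaf in tree.leaves():
        name = fold(leaf.name)
        eff = default
        hit = False
        for i, rule in enumerate(rules):
            ok = (patterns[i] == name if mode == "exact"
                  else patterns[i] in name)
            if ok:
                eff = rule.styles.merged_over(eff)
                used[i] = True
                hit = True
        if hit:
            styles[leaf] = eff
            report.n_matched_leaves += 1
        else:
            report.unmatched_leaves.append(leaf.name)
    report.unused_rules = [r.pattern for r, u in zip(rules, used) if not u]
    return ResolvedStyles(styles, default), report


_MIXED = object()


def propagate_styles(tree: Tree, leaf_styles: ResolvedStyles) -> ResolvedStyles:
    """Style inner nodes to match their descendant leaves.

    For each style field independently, an inner node receives value v iff
    every descendant leaf's effective value equals v (the default counts as
    a value); otherwise the inner node keeps the default for that field.
    One post-order pass; idempotent.
    """
    default = leaf_styles.default
    # per node: tuple of per-field values, _MIXED marking disagreement
    agg: dict[Node, tuple] = {}
    styles: dict[Node, StyleSet] = {}
    for node in iter_postorder(tree.root):
        if node.is_leaf:
            eff = leaf_styles.effective(node)
            agg[node] = tuple(getattr(eff, f) for f in _ALL_FIELDS)
            if eff != default:
                styles[node] = eff
            continue
        first = agg[node.children[0]]
        merged = list(first)
        for child in node.children[1:]:
            other = agg[child]
            for i, v in enumerate(merged):
                if v is not _MIXED and v != other[i]:
                    merged[i] = _MIXED
        agg[node] = tuple(merged)
        updates = {
            f: v for f, v in zip(_ALL_FIELDS, merged)
            if v is not _MIXED
        }
        eff = replace(default, **updates) if updates else default
        if eff != default:
            styles[node] = eff
    return ResolvedStyles(styles, default)


def support_decorations(tree: Tree, filled_min: float,
                        open_min: float) -> dict[Node, str]:
    """Classify inner nodes by numeric support label.

    Returns ``{node: "filled" | "open"}`` for inner nodes whose
    ``inner_label`` parses as a number s with s >= ``filled_min`` (filled)
    or ``open_min`` <= s < ``filled_min`` (open); other inner nodes are
    omitted (no decoration).  Thresholds are on whatever scale the labels
    use (percent or 0-1).
    """
    if open_min > filled_min:
        raise ValueError(
            f"open_min ({open_min}) must be <= filled_min ({filled_min})")
    out: dict[Node, str] = {}
    stack = [tree.root]
    while stack:
        node = stack.pop()
        stack.extend(node.children)
        if node.is_leaf or node.inner_label is None:
            continue
        try:
            s = float(node.inner_label)
        except ValueError:
            continue
        if s >= filled_min:
            out[node] = "filled"
        elif s >= open_min:
            out[node] = "open"
    return out
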