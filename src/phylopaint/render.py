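"""Styled SVG rendering of laid-out trees.

Produces standalone SVG 1.1 documents.  Drawing rules:

* one edge element per non-root node — a right-angle "elbow" in rectangular
  mode, a circumferential arc plus a radial segment in circular mode, and a
  straight line in the radial layout;
* one text element per leaf when labels are shown (the ``new_name`` style
  replaces the displayed text; in the polar modes labels rotate to the leaf
  angle and flip on the left half for readability);
* leaf dots as circles where a ``leaf_dot_color`` is styled;
* bar series as rectangles beyond the leaf tips (rectangular) or outward
  annular wedges (circular), scaled so the largest |height| in a series
  renders at ``bar_max_length``; negative heights draw in the same
  direction and may be flagged with ``bar_negative_color``;
* arcs as fixed-thickness ring segments (or strips, in rectangular mode)
  spanning each leaf's slot;
* support decorations as filled/open circles at inner-node positions.

Output is deterministic: elements are emitted in depth-first tree order and
all coordinates are formatted with 4 decimal places, so identical inputs
yield byte-identical documents.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional
from xml.sax.saxutils import escape

from .layout import LayoutResult, Placement
from .mapping import Node, ResolvedStyles, StyleSet, Tree
from .newick_io import iter_preorder

__all__ = ["RenderOptions", "render_svg"]


@dataclass
class RenderOptions:
    """Canvas geometry and feature toggles; sizes in px."""

    width: float = 800.0
    height: float = 600.0
    show_labels: bool = True
    show_dots: bool = True
    show_bars: bool = True
    show_arcs: bool = True
    show_support: bool = True
    bar_max_length: float = 60.0
    label_default_size: float = 12.0
    branch_default_color: str = "#000000"
    branch_default_width: float = 1.0
    background: Optional[str] = None
    margin: float = 20.0
    label_gap: float = 4.0
    series_padding: float = 6.0
    arc_thickness: float = 10.0
    leaf_dot_default_size: float = 3.0
    bar_default_color: str = "#808080"
    bar_negative_color: Optional[str] = None
    support_radius: float = 3.5

    def __post_init__(self) -> None:
        for name in ("width", "height", "bar_max_length",
                     "label_default_size", "branch_default_width",
                     "leaf_dot_default_size", "support_radius"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def _fmt(v: float) -> str:
    s = f"{v:.4f}"
    return "0.0000" if s == "-0.0000" else s


def _norm_deg(a: float) -> float:
    return a % 360.0


class _Canvas:
    """Maps abstract layout coordinates onto screen pixels.

    Rectangular: x right, y down, root at the left.  Circular: polar about
    the canvas center, rotated so the first leaf (layout angle 0) sits at
    the top.  Radial: Cartesian about the center with y flipped so layout
    angles keep their chirality on screen.
    """

    def __init__(self, tree: Tree, layout: LayoutResult,
                 opts: RenderOptions) -> None:
        self.mode = layout.mode
        self.opts = opts
        label_space = (opts.label_default_size * 8.0
                       if opts.show_labels else 0.0)
        self.annot_offset = opts.label_gap + label_space
        ps = layout.placements
        if self.mode == "rectangular":
            max_x = max(p.x for p in ps) or 1.0
            span_y = max(p.y for p in ps)
            avail = opts.width - 2 * opts.margin - self.annot_offset \
                - self._annot_extent(tree, opts)
            self.sx = max(avail, 1.0) / max_x
            self.sy = (opts.height - 2 * opts.margin) / max(span_y, 1.0)
            self.x0 = opts.margin
            self.y0 = opts.margin
            self.tip_x = self.x0 + max_x * self.sx
        else:
            if self.mode == "circular":
                max_r = max(p.radius or 0.0 for p in ps) or 1.0
            else:
                max_r = max(math.hypot(p.x, p.y) for p in ps) or 1.0
            avail = min(opts.width, opts.height) / 2 - opts.margin \
                - self.annot_offset - self._annot_extent(tree, opts)
            self.scale = max(avail, 1.0) / max_r
            self.cx = opts.width / 2
            self.cy = opts.height / 2
            self.tip_r = max_r * self.scale

    @staticmethod
    def _annot_extent(tree: Tree, opts: RenderOptions) -> float:
        extent = 0.0
        if opts.show_arcs:
            extent += opts.arc_thickness + opts.series_padding
        if opts.show_bars:
            extent += opts.bar_max_length + opts.series_padding
        return extent

    # -- rectangular ------------------------------------------------------
    def rect_pt(self, p: Placement) -> tuple[float, float]:
        return self.x0 + p.x * self.sx, self.y0 + p.y * self.sy

    # -- circular ---------------------------------------------------------
    def circ_pt(self, radius_px: float, angle: float) -> tuple[float, float]:
        """Screen point at a polar position; angle in layout radians."""
        a = angle - math.pi / 2  # first leaf at top
        return (self.cx + radius_px * math.cos(a),
                self.cy + radius_px * math.sin(a))

    def circ_screen_deg(self, angle: float) -> float:
        return _norm_deg(math.degrees(angle - math.pi / 2))

    # -- radial -----------------------------------------------------------
    def rad_pt(self, p: Placement) -> tuple[float, float]:
        return self.cx + p.x * self.scale, self.cy - p.y * self.scale

    def rad_screen_deg(self, angle: float) -> float:
        return _norm_deg(-math.degrees(angle))


def render_svg(tree: Tree, layout: LayoutResult, styles: ResolvedStyles,
               decorations: Optional[dict[Node, str]] = None,
               options: Optional[RenderOptions] = None) -> str:
    """Render the tree to a standalone SVG document string."""
    opts = options or RenderOptions()
    decorations = decorations or {}
    nodes = list(iter_preorder(tree.root))
    if len(layout.placements) != len(nodes) or any(
            n not in layout.by_node for n in nodes):
        raise ValueError("layout does not cover the given tree")
    canvas = _Canvas(tree, layout, opts)
    mode = layout.mode

    out: list[str] = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
        f'width="{_fmt(opts.width)}" height="{_fmt(opts.height)}" '
        f'viewBox="0 0 {_fmt(opts.width)} {_fmt(opts.height)}">',
    ]
    if opts.background:
        out.append(
            f'<rect class="background" x="0" y="0" '
            f'width="{_fmt(opts.width)}" height="{_fmt(opts.height)}" '
            f'fill="{opts.background}"/>')

    parent: dict[Node, Optional[Node]] = {tree.root: None}
    for n in nodes:
        for c in n.children:
            parent[c] = n

    leaves = [n for n in nodes if n.is_leaf]
    slot_ang = 0.0
    if mode == "circular" and len(leaves) > 1:
        a = sorted(layout.by_node[lf].angle for lf in leaves)
        slot_ang = a[1] - a[0]

    # ---- edges ----------------------------------------------------------
    for n in nodes:
        if n is tree.root:
            continue
        eff = styles.effective(n)
        color = eff.branch_color or opts.branch_default_color
        widthpx = eff.branch_width or opts.branch_default_width
        p = layout.by_node[parent[n]]
        c = layout.by_node[n]
        if mode == "rectangular":
            x0, y0 = canvas.rect_pt(p)
            x1, y1 = canvas.rect_pt(c)
            d = (f"M {_fmt(x0)} {_fmt(y0)} V {_fmt(y1)} H {_fmt(x1)}")
        elif mode == "circular":
            pr = (p.radius or 0.0) * canvas.scale
            cr = (c.radius or 0.0) * canvas.scale
            pa, ca = p.angle or 0.0, c.angle or 0.0
            ex, ey = canvas.circ_pt(cr, ca)
            if pr <= 1e-9 or abs(ca - pa) <= 1e-12:
                sx, sy = canvas.circ_pt(pr, ca)
                d = f"M {_fmt(sx)} {_fmt(sy)} L {_fmt(ex)} {_fmt(ey)}"
            else:
                sx, sy = canvas.circ_pt(pr, pa)
                mx, my = canvas.circ_pt(pr, ca)
                laf = 1 if abs(ca - pa) > math.pi else 0
                sf = 1 if ca > pa else 0
                d = (f"M {_fmt(sx)} {_fmt(sy)} "
                     f"A {_fmt(pr)} {_fmt(pr)} 0 {laf} {sf} "
                     f"{_fmt(mx)} {_fmt(my)} L {_fmt(ex)} {_fmt(ey)}")
        else:  # radial
            x0, y0 = canvas.rad_pt(p)
            x1, y1 = canvas.rad_pt(c)
            d = f"M {_fmt(x0)} {_fmt(y0)} L {_fmt(x1)} {_fmt(y1)}"
        out.append(
            f'<path class="edge" d="{d}" fill="none" stroke="{color}" '
            f'stroke-width="{_fmt(widthpx)}"/>')

    # ---- leaf labels ----------------------------------------------------
    if opts.show_labels:
        for n in leaves:
            eff = styles.effective(n)
            text = escape(eff.new_name if eff.new_name is not None else n.name)
            color = eff.label_color or "#000000"
            size = eff.label_font_size or opts.label_default_size
            pl = layout.by_node[n]
            if mode == "rectangular":
                x, y = canvas.rect_pt(pl)
                out.append(
                    f'<text class="leaf-label" x="{_fmt(x + opts.label_gap)}" '
                    f'y="{_fmt(y)}" dy="0.32em" font-size="{_fmt(size)}" '
                    f'fill="{color}">{text}</text>')
            else:
                if mode == "circular":
                    r = (pl.radius or 0.0) * canvas.scale + opts.label_gap
                    x, y = canvas.circ_pt(r, pl.angle or 0.0)
                    deg = canvas.circ_screen_deg(pl.angle or 0.0)
                else:
                    bx, by = canvas.rad_pt(pl)
                    ang = pl.angle or 0.0
                    deg = canvas.rad_screen_deg(ang)
                    x = bx + opts.label_gap * math.cos(math.radians(deg))
                    y = by + opts.label_gap * math.sin(math.radians(deg))
                anchor = "start"
                if 90.0 < deg < 270.0:
                    deg = _norm_deg(deg + 180.0)
                    anchor = "end"
                out.append(
                    f'<text class="leaf-label" x="{_fmt(x)}" y="{_fmt(y)}" '
                    f'dy="0.32em" font-size="{_fmt(size)}" fill="{color}" '
                    f'text-anchor="{anchor}" '
                    f'transform="rotate({_fmt(deg)} {_fmt(x)} {_fmt(y)})">'
                    f'{text}</text>')

    # ---- leaf dots ------------------------------------------------------
    if opts.show_dots:
        for n in leaves:
            eff = styles.effective(n)
            if eff.leaf_dot_color is None:
                continue
            r = eff.leaf_dot_size or opts.leaf_dot_default_size
            pl = layout.by_node[n]
            if mode == "rectangular":
                x, y = canvas.rect_pt(pl)
            elif mode == "circular":
                x, y = canvas.circ_pt((pl.radius or 0.0) * canvas.scale,
                                      pl.angle or 0.0)
            else:
                x, y = canvas.rad_pt(pl)
            out.append(
                f'<circle class="leaf-dot" cx="{_fmt(x)}" cy="{_fmt(y)}" '
                f'r="{_fmt(r)}" fill="{eff.leaf_dot_color}"/>')

    # ---- arcs & bars (rectangular / circular annotation bands) ----------
    band = canvas.annot_offset
    if opts.show_arcs and mode in ("rectangular", "circular"):
        drew = _render_arcs(out, tree, layout, styles, canvas, opts,
                            leaves, slot_ang, band)
        if drew:
            band += opts.arc_thickness + opts.series_padding
    if opts.show_bars and mode in ("rectangular", "circular"):
        _render_bars(out, layout, styles, canvas, opts, leaves, slot_ang,
                     band)

    # ---- support decorations -------------------------------------------
    if opts.show_support:
        for n in nodes:
            deco = decorations.get(n)
            if deco is None or n.is_leaf:
                continue
            pl = layout.by_node[n]
            if mode == "rectangular":
                x, y = canvas.rect_pt(pl)
            elif mode == "circular":
                x, y = canvas.circ_pt((pl.radius or 0.0) * canvas.scale,
                                      pl.angle or 0.0)
            else:
                x, y = canvas.rad_pt(pl)
            if deco == "filled":
                fill, stroke = "#000000", "none"
            else:
                fill, stroke = "#FFFFFF", "#000000"
            out.append(
                f'<circle class="support support-{deco}" cx="{_fmt(x)}" '
                f'cy="{_fmt(y)}" r="{_fmt(opts.support_radius)}" '
                f'fill="{fill}" stroke="{stroke}"/>')

    out.append("</svg>")
    return "\n".join(out) + "\n"


def _render_arcs(out, tree, layout, styles, canvas, opts, leaves,
                 slot_ang, band) -> bool:
    drew = False
    for n in leaves:
        eff = styles.effective(n)
        if eff.arc_color is None:
            continue
        drew = True
        pl = layout.by_node[n]
        if canvas.mode == "rectangular":
            _, y = canvas.rect_pt(pl)
            x = canvas.tip_x + band
            out.append(
                f'<rect class="arc" x="{_fmt(x)}" '
                f'y="{_fmt(y - canvas.sy / 2)}" '
                f'width="{_fmt(opts.arc_thickness)}" '
                f'height="{_fmt(canvas.sy)}" fill="{eff.arc_color}"/>')
        else:
            r0 = canvas.tip_r + band
            r1 = r0 + opts.arc_thickness
            a = pl.angle or 0.0
            out.append(_annular_wedge(
                canvas, "arc", r0, r1, a - slot_ang / 2, a + slot_ang / 2,
                eff.arc_color))
    return drew


def _render_bars(out, layout, styles, canvas, opts, leaves, slot_ang,
                 band) -> None:
    n_series = max((len(styles.effective(n).bar_values) for n in leaves),
                   default=0)
    for s in range(n_series):
        heights = [abs(styles.effective(n).bar_values[s][0])
                   for n in leaves
                   if len(styles.effective(n).bar_values) > s]
        peak = max(heights, default=0.0)
        if peak == 0.0:
            continue
        px_per_unit = opts.bar_max_length / peak
        offset = band + s * (opts.bar_max_length + opts.series_padding)
        for n in leaves:
            bv = styles.effective(n).bar_values
            if len(bv) <= s:
                continue
            h, color = bv[s]
            if h == 0.0:
                continue
            fill = color or opts.bar_default_color
            if h < 0 and opts.bar_negative_color:
                fill = opts.bar_negative_color
            length = abs(h) * px_per_unit
            pl = layout.by_node[n]
            if canvas.mode == "rectangular":
                _, y = canvas.rect_pt(pl)
                x = canvas.tip_x + offset
                out.append(
                    f'<rect class="bar bar-s{s + 1}" x="{_fmt(x)}" '
                    f'y="{_fmt(y - canvas.sy * 0.4)}" '
                    f'width="{_fmt(length)}" '
                    f'height="{_fmt(canvas.sy * 0.8)}" fill="{fill}"/>')
            else:
                r0 = canvas.tip_r + offset
                a = pl.angle or 0.0
                half = slot_ang * 0.4
                out.append(_annular_wedge(
                    canvas, f"bar bar-s{s + 1}", r0, r0 + length,
                    a - half, a + half, fill))


def _annular_wedge(canvas: _Canvas, cls: str, r0: float, r1: float,
                   a0: float, a1: float, fill: str) -> str:
    laf = 1 if abs(a1 - a0) > math.pi else 0
    p1 = canvas.circ_pt(r0, a0)
    p2 = canvas.circ_pt(r1, a0)
    p3 = canvas.circ_pt(r1, a1)
    p4 = canvas.circ_pt(r0, a1)
    d = (f"M {_fmt(p1[0])} {_fmt(p1[1])} L {_fmt(p2[0])} {_fmt(p2[1])} "
         f"A {_fmt(r1)} {_fmt(r1)} 0 {laf} 1 {_fmt(p3[0])} {_fmt(p3[1])} "
         f"L {_fmt(p4[0])} {_fmt(p4[1])} "
         f"A {_fmt(r0)} {_fmt(r0)} 0 {laf} 0 {_fmt(p1[0])} {_fmt(p1[1])} Z")
    return f'<path class="{cls}" d="{d}" fill="{fill}"/>'
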