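"""Count-table reductions and color gradients.

Reduces an M x N count table (one row per observation, e.g. an OTU, one
column per variable, e.g. a sample) to a single scalar per observation —
the row mean, Pielou's evenness, or the first principal-component score —
then min-max scales the scalars onto [0, 1] and evaluates a color gradient
at each, producing a mapping file for the tree viewer.

Evenness for observation i with row proportions p_ij = c_ij / sum_j c_ij is

    E_i = H_i / H_max = (-sum_j p_ij log2 p_ij) / log2 N,

i.e. the Shannon entropy of the row composition over its maximum (a
uniform row gives E = 1, a single-support row E = 0).  The projection mode
runs PCA via SVD of the column-centered (optionally unit-variance scaled)
matrix X = U S V^T; the PC-1 scores are the first column of U S, with the
sign fixed so the largest-magnitude loading in V's first column is
positive.

Gradients are either ordered RGB color stops (interpolated linearly per
channel) or the cubehelix scheme: with phi = 2*pi*(s/3 + r*lambda),
g = lambda**gamma and a = h*g*(1-g)/2,

    R = g + a*(-0.14861*cos phi + 1.78277*sin phi)
    G = g + a*(-0.29227*cos phi - 0.90649*sin phi)
    B = g + a*( 1.97294*cos phi),

each channel clamped to [0, 1] before quantization to 0-255.  Interpolation
is in raw RGB (exactly testable; a known perceptual tradeoff).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .mapping import _BAR_RE, _COLOR_COLUMNS, normalize_hex

__all__ = [
    "CountTable",
    "ReductionResult",
    "Gradient",
    "CountTableParseError",
    "PALETTES",
    "parse_count_table",
    "reduce_mean",
    "reduce_evenness",
    "reduce_projection",
    "scale_unit_interval",
    "color_at",
    "colorize",
    "write_gradient_mapping",
]


class CountTableParseError(ValueError):
    def __init__(self, message: str, row: Optional[int] = None,
                 col: Optional[int] = None) -> None:
        loc = ""
        if row is not None:
            loc = f" (row {row}" + (f", column {col})" if col else ")")
        super().__init__(message + loc)
        self.row = row
        self.col = col


@dataclass
class CountTable:
    """M observations x N variables of finite reals."""

    observation_names: list[str]
    variable_names: list[str]
    values: np.ndarray  # shape (M, N), float64

    @property
    def m(self) -> int:
        return len(self.observation_names)

    @property
    def n(self) -> int:
        return len(self.variable_names)


@dataclass
class ReductionResult:
    """Per-observation scalar, its [0,1] min-max scaling, and (optionally)
    the hex color the gradient assigns to it."""

    observation_names: list[str]
    raw_scores: np.ndarray
    scaled: np.ndarray
    colors: Optional[list[str]] = None
    kind: str = ""


def parse_count_table(text: str) -> CountTable:
    """Parse a classic-style tab-separated count table.

    The file has M+1 rows (first row is the header) and N+1 columns (first
    column holds observation names).  Cells must be numeric; negatives are
    accepted (general numeric data).
    """
    lines = text.split("\n")
    if lines and lines[-1] == "":
        lines.pop()
    lines = [ln[:-1] if ln.endswith("\r") else ln for ln in lines]
    if not lines:
        raise CountTableParseError("empty table: missing header", row=1)
    header = lines[0].split("\t")
    if len(header) < 2:
        raise CountTableParseError(
            "header must have at least one variable column", row=1)
    variable_names = header[1:]
    if len(lines) < 2:
        raise CountTableParseError("table has no data rows", row=2)
    names: list[str] = []
    rows: list[list[float]] = []
    for row_no, line in enumerate(lines[1:], start=2):
        cells = line.split("\t")
        if len(cells) != len(header):
            raise CountTableParseError(
                f"ragged row: {len(cells)} cells, expected {len(header)}",
                row=row_no)
        names.append(cells[0])
        vals = []
        for col_no, cell in enumerate(cells[1:], start=2):
            try:
                v = float(cell)
            except ValueError:
                raise CountTableParseError(
                    f"non-numeric cell {cell!r}", row=row_no, col=col_no
                ) from None
            if not math.isfinite(v):
                raise CountTableParseError(
                    f"non-finite cell {cell!r}", row=row_no, col=col_no)
            vals.append(v)
        rows.append(vals)
    return CountTable(names, variable_names,
                      np.asarray(rows, dtype=np.float64))


# ---------------------------------------------------------------------------
# Reductions
# ---------------------------------------------------------------------------

def scale_unit_interval(scores: Sequence[float]) -> np.ndarray:
    """Min-max transform onto [0, 1]; all-equal inputs map to 0.5."""
    arr = np.asarray(scores, dtype=np.float64)
    if arr.size == 0:
        raise ValueError("need at least one score")
    if not np.all(np.isfinite(arr)):
        raise ValueError("scores must be finite")
    lo, hi = arr.min(), arr.max()
    if hi == lo:
        return np.full(arr.shape, 0.5)
    return (arr - lo) / (hi - lo)


def _result(table: CountTable, raw: np.ndarray, kind: str,
            gradient: Optional["Gradient"]) -> ReductionResult:
    scaled = scale_unit_interval(raw)
    res = ReductionResult(list(table.observation_names), raw, scaled,
                          kind=kind)
    if gradient is not None:
        res.colors = [color_at(gradient, lam) for lam in scaled]
    return res


def reduce_mean(table: CountTable, gradient: Optional["Gradient"] = None,
                kind: str = "mean") -> ReductionResult:
    """Row means (``kind="mean"``) or row sums (``kind="sum"``)."""
    if kind not in ("mean", "sum"):
        raise ValueError(f"kind must be 'mean' or 'sum', got {kind!r}")
    raw = table.values.sum(axis=1)
    if kind == "mean":
        raw = raw / table.n
    return _result(table, raw, kind, gradient)


def reduce_evenness(table: CountTable,
                    gradient: Optional["Gradient"] = None) -> ReductionResult:
    """Pielou's evenness per row, with the 0*log(0) = 0 convention."""
    if table.n < 2:
        raise ValueError(
            "evenness requires at least 2 variables (log2 N > 0)")
    vals = table.values
    if np.any(vals < 0):
        i, j = map(int, np.argwhere(vals < 0)[0])
        raise ValueError(
            f"negative value for observation "
            f"{table.observation_names[i]!r}, variable "
            f"{table.variable_names[j]!r}")
    sums = vals.sum(axis=1)
    zero = np.nonzero(sums == 0)[0]
    if zero.size:
        raise ValueError(
            f"zero-sum row for observation "
            f"{table.observation_names[int(zero[0])]!r}")
    p = vals / sums[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log2(p), 0.0)
    h = -terms.sum(axis=1) + 0.0  # normalize -0.0 for zero-entropy rows
    raw = h / math.log2(table.n)
    return _result(table, raw, "evenness", gradient)


def reduce_projection(table: CountTable, scale_variables: bool = False,
                      gradient: Optional["Gradient"] = None) -> ReductionResult:
    """PC-1 scores from the SVD of the centered (optionally scaled) matrix.

    Columns are centered; with ``scale_variables`` they are also divided by
    their sample standard deviation (M-1 denominator; zero-variance columns
    are left centered only).  The PC-1 sign is fixed so the loading of
    largest absolute value in V's first column is positive (ties broken by
    the earliest such entry).
    """
    if table.m < 2:
        raise ValueError("projection requires at least 2 observations")
    x = table.values - table.values.mean(axis=0, keepdims=True)
    if scale_variables:
        sd = table.values.std(axis=0, ddof=1)
        nonzero = sd > 0
        if not np.all(nonzero):
            import logging
            logging.getLogger(__name__).warning(
                "%d zero-variance column(s) left centered only",
                int((~nonzero).sum()))
        x = np.where(nonzero[None, :], x / np.where(nonzero, sd, 1.0), x)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    scores = u[:, 0] * s[0]
    loadings = vt[0]
    pivot = int(np.argmax(np.abs(loadings)))
    if loadings[pivot] < 0:
        scores = -scores
    return _result(table, scores, "projection", gradient)


# ---------------------------------------------------------------------------
# Gradients
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Gradient:
    """Either ordered color stops or a cubehelix parameterization.

    ``stops`` is a tuple of (position, "#RRGGBB") pairs with positions
    strictly increasing from 0 to 1.  Cubehelix parameters follow the
    scheme's source: start color ``s``, ``rotations``, ``hue`` saturation
    and ``gamma`` intensity correction.
    """

    kind: str  # "stops" | "cubehelix"
    stops: tuple[tuple[float, str], ...] = ()
    start: float = 0.5
    rotations: float = -1.5
    hue: float = 1.0
    gamma: float = 1.0

    def __post_init__(self) -> None:
        if self.kind == "stops":
            if len(self.stops) < 2:
                raise ValueError("need at least 2 color stops")
            pos = [p for p, _ in self.stops]
            if pos[0] != 0.0 or pos[-1] != 1.0:
                raise ValueError("stops must start at 0 and end at 1")
            if any(b <= a for a, b in zip(pos, pos[1:])):
                raise ValueError("stop positions must be strictly increasing")
        elif self.kind != "cubehelix":
            raise ValueError(f"unknown gradient kind {self.kind!r}")

    @classmethod
    def from_colors(cls, colors: Sequence[str]) -> "Gradient":
        """Evenly spaced stops from an ordered list of >= 2 hex colors."""
        n = len(colors)
        if n < 2:
            raise ValueError("need at least 2 colors")
        stops = tuple(
            (i / (n - 1), normalize_hex(c)) for i, c in enumerate(colors))
        return cls("stops", stops=stops)

    @classmethod
    def cubehelix(cls, start: float = 0.5, rotations: float = -1.5,
                  hue: float = 1.0, gamma: float = 1.0) -> "Gradient":
        return cls("cubehelix", start=start, rotations=rotations, hue=hue,
                   gamma=gamma)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def _hex_to_rgb(color: str) -> tuple[int, int, int]:
    c = normalize_hex(color)
    return int(c[1:3], 16), int(c[3:5], 16), int(c[5:7], 16)


def color_at(gradient: Gradient, lam: float) -> str:
    """Evaluate the gradient at position ``lam`` in [0, 1] -> ``#RRGGBB``."""
    if not (0.0 <= lam <= 1.0):
        raise ValueError(f"position must be in [0, 1], got {lam}")
    if gradient.kind == "cubehelix":
        phi = 2.0 * math.pi * (gradient.start / 3.0 + gradient.rotations * lam)
        g = lam ** gradient.gamma
        a = gradient.hue * g * (1.0 - g) / 2.0
        cp, sp = math.cos(phi), math.sin(phi)
        rgb = (
            g + a * (-0.14861 * cp + 1.78277 * sp),
            g + a * (-0.29227 * cp - 0.90649 * sp),
            g + a * (1.97294 * cp),
        )
        chans = [_round_half_up(min(1.0, max(0.0, v)) * 255.0) for v in rgb]
    else:
        stops = gradient.stops
        hi = next(i for i, (p, _) in enumerate(stops) if p >= lam)
        if stops[hi][0] == lam:
            chans = list(_hex_to_rgb(stops[hi][1]))
        else:
            lo = hi - 1
            p0, c0 = stops[lo]
            p1, c1 = stops[hi]
            t = (lam - p0) / (p1 - p0)
            rgb0, rgb1 = _hex_to_rgb(c0), _hex_to_rgb(c1)
            chans = [_round_half_up(a + (b - a) * t)
                     for a, b in zip(rgb0, rgb1)]
    return "#{:02X}{:02X}{:02X}".format(*chans)


def colorize(reduction: ReductionResult, gradient: Gradient) -> ReductionResult:
    """Fill (or replace) the colors of a reduction in place; returns it."""
    reduction.colors = [color_at(gradient, lam) for lam in reduction.scaled]
    return reduction


# Named palettes are data (ordered stop lists), not code.
PALETTES: dict[str, Gradient] = {
    "viridis": Gradient.from_colors(
        ["#440154", "#46327E", "#365C8D", "#277F8E", "#1FA187", "#4AC16D",
         "#A0DA39", "#FDE725"]),
    "magma": Gradient.from_colors(
        ["#000004", "#3B0F70", "#8C2981", "#DE4968", "#FE9F6D", "#FCFDBF"]),
    "blues": Gradient.from_colors(
        ["#F7FBFF", "#C6DBEF", "#6BAED6", "#2171B5", "#08306B"]),
    "greens": Gradient.from_colors(
        ["#F7FCF5", "#C7E9C0", "#74C476", "#238B45", "#00441B"]),
    "rdylbu": Gradient.from_colors(
        ["#D73027", "#FC8D59", "#FEE090", "#FFFFBF", "#E0F3F8", "#91BFDB",
         "#4575B4"]),
    "spectral": Gradient.from_colors(
        ["#9E0142", "#F46D43", "#FEE08B", "#FFFFBF", "#E6F598", "#66C2A5",
         "#5E4FA2"]),
    "cubehelix": Gradient.cubehelix(),
}


def write_gradient_mapping(table: CountTable, reduction: ReductionResult,
                           target_field: str = "branch_color") -> str:
    """Emit a two-column mapping file assigning each observation its color.

    ``target_field`` must be a recognized color column of the mapping-file
    vocabulary; the output parses with the mapping module.
    """
    ok = target_field in _COLOR_COLUMNS
    m = _BAR_RE.match(target_field)
    if m and m.group(2) == "color":
        ok = True
    if not ok:
        raise ValueError(
            f"target_field {target_field!r} is not a color style column")
    if reduction.colors is None:
        raise ValueError("reduction has no colors; apply a gradient first")
    if len(reduction.colors) != table.m:
        raise ValueError("reduction does not match the table")
    lines = [f"name\t{target_field}"]
    lines.extend(
        f"{name}\t{color}"
        for name, color in zip(table.observation_names, reduction.colors))
    return "\n".join(lines) + "\n"
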