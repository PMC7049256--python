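# Methods

This note records the models, conventions and numerical choices behind
`phylopaint`, in the order the pipeline runs.

## Newick dialect

The parser accepts a single `;`-terminated statement. Single-quoted labels
use `''` as the escape for a literal quote; underscores are **not**
converted to spaces (safer for exact matching of accession-style names);
bracketed comments `[...]` are discarded; the token between `)` and `:` is
stored as the inner node's label (typically bootstrap support). Branch
lengths must be finite and ≥ 0; a tree in which any non-root node lacks a
length is treated as a cladogram downstream. Multifurcations and
single-child nodes pass through untouched — there is no rerooting,
binarization or ladderizing, so support labels stay attached to the inner
node exactly as parsed. Errors report the character offset. Both the
parser and the serializer are iterative (explicit stacks), so caterpillar
trees with 10⁶ leaves are handled without recursion-depth failures; this
is covered by tests.

On output, labels containing whitespace or Newick metacharacters are
single-quoted. Round-tripping preserves topology, names, lengths and inner
labels exactly.

## Layouts

**Rectangular.** Leaves receive transverse coordinates 0, 1, 2, … in
depth-first child order; an inner node sits at the midpoint of its first
and last child (the cluster-dendrogram rule; a `mean`-of-children variant
is available via `inner_rule`). The longitudinal coordinate is the
cumulative branch length from the root, or, in cladogram mode (requested,
or forced when lengths are missing — a warning is logged), the hop depth
with all leaves aligned at the maximum depth.

**Circular.** The polar transform of the rectangular layout: leaf k of n
gets angle k·sweep/n (default sweep 360°, configurable down for a label
gap; values outside (0, 360] are rejected) and radius equal to the
longitudinal coordinate. Angles are radians, 0 along +x, counterclockwise;
the renderer rotates the drawing so the first leaf sits at the top.

**Radial.** The equal-wedge algorithm: the root owns [0, 2π); in
pre-order, each child is allocated a consecutive sub-wedge of width
2π · leaves(child)/leaves(root) starting at its parent's wedge start, and
is placed at parent + branch_length · (cos τ, sin τ) with τ the wedge
bisector. Cladograms substitute unit branch lengths (with a warning).
Consequences used as test oracles: every parent→child Euclidean distance
equals the child's branch length, and sibling wedges exactly partition the
parent wedge.

Zero-length branches are allowed (coincident points render fine). All
layouts are deterministic: identical input gives bit-identical
coordinates.

## Mapping files and style resolution

The column vocabulary (`branch_color`, `branch_width`, `label_color`,
`label_font_size`, `new_name`, `leaf_dot_color`, `leaf_dot_size`,
`bar{k}_height`, `bar{k}_color`, `arc_color`) was chosen to cover every
stylable aspect; unrecognized headers are ignored with a warning so files
carrying extra metadata columns still load. Cells are split on tabs only —
no quoting or escaping — and empty cells mean "unspecified". Hex colors
accept `#RGB` (expanded) and `#RRGGBB`, normalized to uppercase.

Matching is plain substring or exact equality (never regex), case
sensitive by default with an explicit `--case-insensitive` flag:
predictable behavior matters more than power when patterns are accession
prefixes. All matching rules apply in file order, later rules overriding
earlier ones *field by field*, so a file can layer one concern per block
of rows. `new_name` applies at render time only; matching always uses the
original label. Duplicate leaf names each match independently.

Propagation is a single post-order pass per tree (all fields at once): a
node's per-field value is the children's common value, or a `mixed` marker
on any disagreement; `mixed` converts to the default at the end but stays
`mixed` while ascending — this is what makes the pass equal the
brute-force "compare all descendant leaves" definition, which the tests
run as an independent oracle. The default counts as a value: a clade of
one styled and one unstyled leaf gets the default, not the style.
Propagation is idempotent and fields never interact.

Support decorations: an inner node whose label parses as a number s gets a
filled circle if s ≥ filled_min, an open circle if open_min ≤ s <
filled_min, nothing otherwise (including non-numeric labels). Thresholds
are on whatever scale the labels use — 95/70 for percent bootstraps,
0.95/0.70 for posterior probabilities.

## Count-table reductions

The mean reduction divides by N; a `sum` variant is provided for users who
want the raw row total (after min-max scaling the two give identical
colors, so the distinction only matters if raw scores are inspected).

Evenness requires N ≥ 2, non-negative cells and positive row sums
(violations raise errors naming the observation); 0·log 0 is taken as 0.
E is invariant under positive row scaling and column permutation, strictly
below 1 for non-uniform rows — both property-tested.

The projection centers columns; with `scale_variables` it also divides by
the sample standard deviation (M−1 denominator), leaving zero-variance
columns centered only (warning). Scores are the first column of US from
`numpy.linalg.svd`. SVD sign ambiguity is fixed by requiring the
largest-|loading| entry of V's first column to be positive (ties: earliest
entry), which makes scores reproducible across runs and row orderings.
Whether to scale scores by the singular value is immaterial here because
min-max scaling absorbs any affine transform.

Scaling onto [0, 1] is min-max (not rank or quantile): it preserves the
shape of the score distribution, and degenerate all-equal scores map to
0.5 (the gradient midpoint) rather than an arbitrary end.

## Color math

Stop gradients interpolate linearly per RGB channel between bracketing
stops, rounding half-up to integer channels — raw RGB rather than Lab/HCL
is a deliberate tradeoff: exact, platform-independent testability over
perceptual uniformity. Named palettes (viridis-, ColorBrewer-style) are
stored as data (ordered stop lists) and validated by the same invariant as
user-supplied stops (strictly increasing positions, 0 to 1).

Cubehelix uses its defining formula — φ = 2π(s/3 + rλ), g = λ^γ,
a = h·g(1−g)/2, with the fixed RGB rotation coefficients — with defaults
s = 0.5, r = −1.5, h = 1.0, γ = 1.0 (the scheme's published defaults).
Channels are clamped to [0, 1] *before* quantization because the helix can
leave the RGB cube at high hue. λ = 0 is always black; λ = 1 is white
whenever γ = 1.

## Rendering

SVG 1.1, standalone, elements emitted in depth-first tree order with all
floats fixed at 4 decimals — identical inputs give byte-identical
documents, enabling golden-file tests. Edges are right-angle elbows
(rectangular), an arc at the parent radius plus a radial segment
(circular), or straight lines (radial); elbows match the dendrogram idiom
the layouts implement. One edge per non-root node, one label per leaf when
shown, one dot per dot-styled leaf — these element-count laws are tested
via an independent XML parser. Polar labels rotate to the leaf angle and
flip (with `text-anchor: end`) on the left half for readability.

Bar series scale so the largest |height| in a series renders at
`bar_max_length`; zero heights draw nothing; negative heights draw in the
same direction and can be flagged with `bar_negative_color` (two-color
sign mode, useful for log-ratios). Series stack outward with fixed
padding. Arcs are fixed-thickness strips (rectangular) or annular wedges
spanning the leaf's angular slot (circular). Bars and arcs are drawn in
the rectangular and circular modes; the radial mode draws branches,
labels, dots and support circles only. Colors are emitted verbatim as
`#RRGGBB`; no opacity in v1. Label extents use a fixed per-character
budget rather than font metrics — collision avoidance is out of scope.

## Synthetic data

The generator grows topology by sequential random attachment — each new
leaf splits a uniformly chosen existing edge — yielding a bifurcating
rooted tree (simpler than Yule/coalescent and sufficient for exercising
parsers and layouts), with i.i.d. uniform(0, 1) branch lengths, the same
law as the standard `rtree`/`runif` stress recipe for million-leaf trees.
Count tables are Poisson (mean 10 per cell by default) with all-zero rows
redrawn so evenness is always defined; mapping files assign random branch
colors but plant one uniformly-colored clade so propagation has a known
positive case. Everything is a pure function of (n_leaves, n_variables,
seed).

What this does **not** emulate: realistic substitution processes, clock
structure, compositional correlation between taxa, or sparse overdispersed
OTU tables. Passing tests therefore demonstrate correctness of parsing,
geometry, propagation, reduction and rendering — not biological realism of
any example figure.

## Problem sizes and determinism

The test suite and `scripts/acceptance.py` use: one 1,000,000-leaf tree
(generation + rectangular layout, about a minute on one core), 500 random
trees (≤ 80 leaves) for round trips, 200 trees (≤ 200 leaves) for the
propagation oracle, 200 trees (≤ 150 leaves) for radial geometry, 1,000
random rows for evenness invariances, and 100 random tables (M ≤ 50,
N ≤ 10) × 1,000 random unit projections for PCA optimality. All randomness
flows from explicit seeds; the acceptance script derives every stream from
its `--seed` argument.

## Known limitations

No NEXUS/PhyloXML/NeXML input, no rerooting or ladderizing, no biom
parsing (convert externally), no PDF/PNG export, no legends, no font
metrics. Interpolation in RGB can pass through muddy midpoints for
complementary color pairs; pick palettes accordingly.
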