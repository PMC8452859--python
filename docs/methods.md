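# Methods

## The model

A Venn diagram over `n` named sets `S_1..S_n` (2 ≤ n ≤ 7) is the pair of a
combinatorial partition and a geometric one, joined by region masks. The
mask `m ∈ {0,1}^n \ {0}` names the region

```
R(m) = ⋂_{i: m_i = 1} S_i  \  ⋃_{i: m_i = 0} S_i
```

applied once to item sets (members, counts, percent of the union) and once
to per-set polygons (region polygons, areas). Because each item/point
belongs to exactly one mask, the 2ⁿ − 1 regions partition the union on both
sides; that partition property — not any particular coordinate set — is
what the package treats as the definition of a correct diagram. Canonical
region order is ascending popcount, then lexicographic mask, which keeps
single-set regions first and is stable across runs.

One set is excluded because it has no overlap structure; more than seven is
excluded because the regions become unreadably small (the error message
points to UpSet plots, the standard alternative at large n).

## Set algebra

Items are opaque strings compared case-sensitively after stripping
surrounding whitespace; within-set duplicates are dropped on ingest with a
logged count. Region membership is computed by set intersection/difference
per mask; the test suite checks it against an independent per-item
classifier (build each item's membership bit-vector directly). Percentages
are shares of the union — a list input has no "outside" items, so the union
is the only meaningful total — rounded half-away-from-zero to one decimal;
with that rule the rounded percents can drift from 100 by at most
0.05·(2ⁿ−1).

## Geometry

All geometry is polygonal, in an abstract [0,1]×[0,1] frame with y up.
Smooth curves are discretized at 720 vertices by default: at that
resolution a unit circle's area errs by ~4·10⁻⁶ relative, comfortably
below the 10⁻³ tolerance used when comparing two-circle intersections with
the closed-form lens area. Rings are explicitly closed, consecutive
duplicate vertices removed, zero-area rings dropped, and self-intersecting
rings rejected with the ring index named. Boolean operations (shapely/GEOS
underneath) share their names and semantics with the item-set operations.

Region decomposition splits the union of all shapes successively by each
set polygon (intersection/difference), so the resulting region polygons are
disjoint by construction and every mask appears exactly once. Slivers with
area below ε = 10⁻⁶ × union area are treated as empty; empty regions keep
their slot (and their counts in tables) but draw no label.

### Layout families

* **classic 2–3**: equal circles (two side by side; three on an equilateral
  triangle) — the only arrangements most readers have seen.
* **classic 4**: four congruent 2:1 ellipses at ±45°, centers mirrored
  about the vertical axis. The offsets were tuned once so that all 15
  regions have positive area, then frozen as a packaged coordinate fixture;
  validity is defined by `validate_layout`, not by matching any other
  tool's coordinates.
* **constructive 3–7 (Edwards-style)**: set 1 a half-plane (x > ½ clipped
  to the frame), set 2 the perpendicular half-plane, set 3 a disc of radius
  r = 0.25, and each further set k ≥ 4 a "cogwheel" disc whose boundary is
  the square wave ρ(θ) = r + h_k·sign(cos(2^{k−3} θ)) with amplitudes
  h_k = 0.11·0.45^{k−4}, i.e. 2^{k−3} teeth weaving across the disc
  boundary. The cosine phase makes the sign change points of all waves
  distinct and places every sign combination of the gear waves inside every
  quadrant; picking θ with the desired sign pattern and a radius just
  inside (or outside) the disc then realizes every mask, so all 2ⁿ − 1
  regions exist by construction. The shrinking amplitudes keep gear
  boundaries from coinciding. Verified by `validate_layout` for n = 3..7.
* **six triangles**: Carroll's configuration of six triangles forming a
  complete 6-set diagram, shipped as a fixture and rebuilt through the
  `triangle()` primitive; it demonstrates that a full 63-region diagram
  needs nothing beyond three-vertex polygons.
* **rounded rectangles**: the four-ellipse arrangement with elongated
  rounded rectangles substituted, shipped as a fixture.

`validate_layout` reports the number of positive-area regions (expected
2ⁿ − 1), the maximum pairwise region overlap (STRtree-prefiltered), and the
gap between the summed region areas and the union area, both against ε;
a layout is valid iff all three checks pass. Custom layouts that fail are
not rejected — the report travels as a warning on the plot data so
exploratory shapes still render.

### Label anchors

Region labels sit at the pole of inaccessibility (interior point farthest
from the boundary) of the region's largest part, computed deterministically;
unlike the centroid it stays inside crescents and other non-convex regions.
Set labels default to the shape's boundary point farthest from the layout
centroid, pushed outward by 5% of the layout diameter — outside the drawing
for compact layouts — and user-supplied anchors pass through unchanged.

## Plot data and tables

`VennPlotData` holds `n` set-edge records (boundary polyline, label anchor,
set size) and 2ⁿ − 1 region records (polygon, interior anchor, members,
count, percent), joined by mask; names are derived from masks at join time
so the mask remains the single source of truth. The geometry-first
workflow (`plot_data_from_layout` then `attach_sets`) supports custom
shapes, and attaching is idempotent. The region table is a fixed-order TSV
(`mask, name, count, percent, members`), members sorted and ;-joined, so
repeated exports are byte-identical.

## Rendering

Four independent layers, in z-order: (1) region fills mapped through a
continuous colormap (default `cividis`, perceptually uniform blue→yellow)
with a color-bar legend spanning [min count, max count]; (2) set edges;
(3) set labels; (4) region labels (count and/or percent). Zero-count
regions are filled at the colormap minimum rather than left blank so the
partition stays visible; when all regions share one count the normalization
widens by one unit to avoid a degenerate color scale. Text uses fixed
figure-relative sizes and never auto-hides on overlap. SVG ids follow
`region-<mask>` / `edge-<name>` / `setlabel-<name>` / `regionlabel-<mask>`,
and exports strip timestamps and use a constant id-hash salt, so identical
inputs give byte-identical SVG.

## Synthetic fixtures

The generator works backwards from a prescription: for each mask it mints
fresh unique items (named `<prefix><mask>_<i>`, so misplacements are
self-diagnosing) and inserts them into exactly the flagged sets; the
pipeline must then recover the prescribed counts exactly, which is the
ground-truth oracle used throughout the tests and the acceptance script.
`random_spec` draws the prescription from a uniform multinomial, seeded.
What these fixtures emulate is only the combinatorial structure of real
gene-list comparisons; they say nothing about realistic identifier
vocabularies, set-size imbalance, or correlated membership, so passing
tests certify the partition arithmetic and the join, not any statistical
behaviour on real data.

## Problem sizes and numerical choices

The test suite and the acceptance script use 60–120 items per synthetic
collection, 25–100 fixtures per set count, 720-vertex curves, and the ε
above; together they run in well under a minute. The acceptance script
derives all randomness from its `--seed`. Known limitations: layouts are
fixed shapes, not area-proportional (no Euler diagrams); all curves are
polygonal approximations; region labels in the 6- and 7-set layouts can
collide at small figure sizes since labels never reposition or hide.
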