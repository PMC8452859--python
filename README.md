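# vennkit

Venn diagrams for 2–7 named sets — as queryable data, flat tables, and
publication-quality figures.

In biomedical work (gene lists, compound panels, variant calls, species
inventories) the question "which items are shared by which conditions?" is a
set-partition problem: *n* sets split their union into the 2ⁿ − 1 regions
R(m) = ⋂_{i: mᵢ=1} Sᵢ \ ⋃_{i: mᵢ=0} Sᵢ, indexed by a binary mask
m ∈ {0,1}ⁿ \ {0}. Most plotting tools draw the diagram but hide the
partition. vennkit computes both sides explicitly and joins them by mask:

* **set algebra** — members, counts, and percent-of-union for every region;
* **geometry** — per-set polygons (circles, ellipses, triangles, rounded
  rectangles, or an Edwards-style construction for 5–7 sets), decomposed by
  polygon boolean operations into the same 2ⁿ − 1 regions;
* **plot data** — a layered object holding set edges/labels/sizes and region
  polygons/members/counts/percents, exportable as a TSV region table;
* **rendering** — a four-layer figure (count-mapped region fills with a
  color-bar legend, set edges, set labels, region labels) exported as
  deterministic SVG, PNG, or PDF.

Every built-in layout is validated operationally: exactly 2ⁿ − 1
positive-area, pairwise disjoint regions whose areas sum to the union area.

## Worked example

```python
import vennkit as vk

venn = vk.make_venn({
    "up_day1": ["TP53", "BRCA1", "EGFR", "MYC", "KRAS"],
    "up_day3": ["BRCA1", "EGFR", "VEGFA", "KRAS", "PTEN", "AKT1"],
    "up_day5": ["EGFR", "VEGFA", "NOTCH1", "KRAS"],
})
pdd = vk.build_plot_data(venn, vk.default_layout(3))
print(vk.to_region_table(pdd).to_string(index=False))
print("shared by all three:", sorted(vk.get_region_items(pdd, "111")))
vk.export(vk.render(pdd), "venn.svg")
```

which prints

```
mask                    name  count percent   members
 001                 up_day5      1   11.1%    NOTCH1
 010                 up_day3      2   22.2% AKT1;PTEN
 100                 up_day1      2   22.2%  MYC;TP53
 011         up_day3/up_day5      1   11.1%     VEGFA
 101         up_day1/up_day5      0    0.0%
 110         up_day1/up_day3      1   11.1%     BRCA1
 111 up_day1/up_day3/up_day5      2   22.2% EGFR;KRAS

shared by all three: ['EGFR', 'KRAS']
```

Each row is one region: its mask (bit *i* = membership of the *i*-th input
set), its name (included set names joined by `/`), how many items fall in
exactly that combination of sets, the share of the union those items
represent, and the items themselves. `venn.svg` shows the same partition
with fills graded by count.

The same pipeline runs from the shell:

```sh
vennkit plot -s up_day1.txt -s up_day3.txt -s up_day5.txt -o venn.svg
vennkit regions -s up_day1.txt -s up_day3.txt -s up_day5.txt -o regions.tsv
```

Inputs can be one-item-per-line files (`--sets`), a two-column
`set_name<TAB>item` TSV (`--tsv`), or a JSON mapping (`--json`); layouts are
`classic` (circles/ellipses, 2–4 sets), `edwards` (constructive, 3–7 sets),
or `custom:<shapes.csv>` with your own coordinates.

## Custom shapes

A layout is just one closed polygon per set. The exchange format is a CSV
with columns `shape_id, ring_id, x, y` (rings explicitly closed; a ring
inside a previous exterior is a hole). The packaged fixtures — the classic
four-ellipse layout, a four-set rounded-rectangle layout, and a six-set
diagram of six triangles (Carroll's configuration) — ship in this format,
and `vennkit.validate_layout` tells you whether any custom arrangement
realizes all 2ⁿ − 1 regions. Invalid exploratory layouts still render; the
validation report travels with the plot data as a warning.

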