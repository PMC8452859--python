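"""The layered plot-data object: geometry joined with set values.

Region masks are the single join key: :func:`~vennkit.geometry.compute_regions`
yields one polygon per mask, :func:`~vennkit.setalgebra.all_regions` one
membership record per mask, and :func:`build_plot_data` zips them into a
:class:`VennPlotData`.  Region names are derived from the mask at join
time so the mask stays the single source of truth.  The object is
queryable (items of any region by mask or name) and exportable as a flat
TSV region table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import pandas as pd

from . import geometry as geo
from . import setalgebra as sa

logger = logging.getLogger("vennkit")

#: Fixed column order of the exported region table.
REGION_TABLE_COLUMNS = ["mask", "name", "count", "percent", "members"]


@dataclass(frozen=True)
class SetEdgeDatum:
    """One set's boundary, label anchor, and size."""

    set_index: int
    name: str
    edge: geo.EdgeLine
    label_anchor: geo.AnchorPoint
    set_size: int


@dataclass(frozen=True)
class RegionDatum:
    """One region's polygon plus its members and statistics.

    ``label_anchor`` is present iff the polygon has positive area;
    zero-area regions keep their counts but draw no label.
    """

    mask: sa.RegionMask
    poly: geo.PolyShape
    label_anchor: geo.AnchorPoint | None
    members: frozenset[str] | None
    count: int | None
    percent: float | None


@dataclass(frozen=True)
class VennPlotData:
    """Everything needed to draw or query one Venn diagram."""

    n: int
    set_edges: tuple[SetEdgeDatum, ...]
    regions: tuple[RegionDatum, ...]
    union_size: int | None
    warnings: tuple[str, ...] = ()
    sep: str = "/"

    @property
    def has_values(self) -> bool:
        return self.union_size is not None

    def region(self, selector: str) -> RegionDatum:
        """Look up a region by mask string ("101") or name ("A/C")."""
        by_mask = {str(r.mask): r for r in self.regions}
        if selector in by_mask:
            return by_mask[selector]
        by_name = {r.mask.name(tuple(e.name for e in self.set_edges), self.sep): r
                   for r in self.regions}
        if selector in by_name:
            return by_name[selector]
        raise sa.VennError(
            f"unknown region {selector!r}; valid masks: {sorted(by_mask)}; "
            f"valid names: {sorted(by_name)}")


def plot_data_from_layout(layout: geo.ShapeLayout,
                          set_names: Sequence[str] | None = None) -> VennPlotData:
    """Geometry-only plot data from a layout (the custom-shape workflow:
    shapes first, values attached later with :func:`attach_sets`)."""
    names = list(set_names) if set_names else [f"Set{i + 1}" for i in range(layout.n)]
    if len(names) != layout.n:
        raise sa.VennError(f"{len(names)} names for {layout.n} shapes")
    regions = geo.compute_regions(layout)
    report = geo.validate_layout(layout, regions=regions)
    warnings = tuple(f"layout: {m}" for m in report.messages)
    for w in warnings:
        logger.warning(w)
    edges = tuple(
        SetEdgeDatum(set_index=i, name=names[i], edge=layout.edges[i],
                     label_anchor=layout.set_label_anchors[i], set_size=0)
        for i in range(layout.n))
    region_data = tuple(
        RegionDatum(mask=r.mask, poly=r.poly,
                    label_anchor=geo.region_label_anchor(r.poly),
                    members=None, count=None, percent=None)
        for r in regions)
    return VennPlotData(n=layout.n, set_edges=edges, regions=region_data,
                        union_size=None, warnings=warnings)


def attach_sets(layout_data: VennPlotData, venn: sa.VennCollection,
                sep: str = "/") -> VennPlotData:
    """Join a collection's region values onto geometry-only plot data.

    Idempotent: attaching a second time overwrites the previous values.
    Layout-validation warnings carried by the geometry are preserved
    (an exploratory invalid layout still renders; the CLI surfaces them).
    """
    if venn.n != layout_data.n:
        raise sa.VennError(f"collection has {venn.n} sets, layout has {layout_data.n}")
    values = {str(m.mask): m for m in sa.all_regions(venn, sep=sep)}
    sizes = dict(sa.set_sizes(venn))
    edges = tuple(replace(e, name=venn.names[e.set_index], set_size=sizes[venn.names[e.set_index]])
                  for e in layout_data.set_edges)
    regions = tuple(
        replace(r, members=values[str(r.mask)].members,
                count=values[str(r.mask)].count,
                percent=values[str(r.mask)].percent)
        for r in layout_data.regions)
    return VennPlotData(n=venn.n, set_edges=edges, regions=regions,
                        union_size=len(venn.union()),
                        warnings=layout_data.warnings, sep=sep)


def build_plot_data(venn: sa.VennCollection, layout: geo.ShapeLayout,
                    sep: str = "/") -> VennPlotData:
    """One-step join of a collection with a layout (the default pipeline)."""
    if venn.n != layout.n:
        raise sa.VennError(f"collection has {venn.n} sets, layout has {layout.n}")
    return attach_sets(plot_data_from_layout(layout, venn.names), venn, sep=sep)


def get_region_items(pd_obj: VennPlotData, selector: str) -> frozenset[str]:
    """Members of one region, selected by mask string or region name."""
    datum = pd_obj.region(selector)
    if datum.members is None:
        raise sa.VennError("plot data carries no set values; attach a collection first")
    return datum.members


def to_region_table(pd_obj: VennPlotData) -> pd.DataFrame:
    """Flat exportable table: mask, name, count, percent, members.

    Rows are in canonical mask order; members are sorted and joined by
    ";" so the output is stable across runs.
    """
    if not pd_obj.has_values:
        raise sa.VennError("plot data carries no set values; attach a collection first")
    names = tuple(e.name for e in pd_obj.set_edges)
    rows = [{
        "mask": str(r.mask),
        "name": r.mask.name(names, pd_obj.sep),
        "count": r.count,
        "percent": f"{r.percent:.1f}%",
        "members": ";".join(sorted(r.members)),
    } for r in pd_obj.regions]
    return pd.DataFrame(rows, columns=REGION_TABLE_COLUMNS)


def region_table_from_collection(venn: sa.VennCollection, sep: str = "/") -> pd.DataFrame:
    """Region table straight from a collection, no geometry involved."""
    rows = [{
        "mask": str(m.mask),
        "name": m.name,
        "count": m.count,
        "percent": f"{m.percent:.1f}%",
        "members": ";".join(sorted(m.members)),
    } for m in sa.all_regions(venn, sep=sep)]
    return pd.DataFrame(rows, columns=REGION_TABLE_COLUMNS)


def write_region_table(pd_obj: VennPlotData, path) -> None:
    """Write the region table as UTF-8 TSV with a header row."""
    to_region_table(pd_obj).to_csv(path, sep="\t", index=False, encoding="utf-8")


def read_region_table(path) -> pd.DataFrame:
    """Read back a region-table TSV (masks kept as strings)."""
    df = pd.read_csv(path, sep="\t", dtype={"mask": str}, keep_default_na=False)
    missing = [c for c in REGION_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise sa.VennError(f"region table is missing columns {missing}")
    return df
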