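"""Four-layer Venn rendering on matplotlib.

Layer 1 fills each region polygon with a continuous colormap mapped to
its item count (or percent), with an automatic color-bar legend; layer 2
draws set edges; layer 3 set labels; layer 4 region labels (count and/or
percent) at each region's interior anchor.  Layers toggle independently.

SVG output is byte-deterministic: element ids are derived from a fixed
hash salt and the timestamp metadata is stripped, so identical plot data
and style produce identical bytes.  Region groups carry the id
``region-<mask>`` and edges ``edge-<set name>``, which makes the figure
layers census-able from the SVG.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from pathlib import Path

import matplotlib as mpl
import numpy as np
from matplotlib.colors import Normalize
from matplotlib.figure import Figure
from matplotlib.patches import PathPatch
from matplotlib.path import Path as MplPath

from .plotdata import VennPlotData
from .setalgebra import VennError

_FORMATS = ("svg", "png", "pdf")
_HASHSALT = "vennkit"


class StyleError(ValueError):
    """Unknown style option or value."""


@dataclass(frozen=True)
class StyleConfig:
    """Rendering options; unknown names are rejected in :meth:`from_dict`."""

    colormap: str = "cividis"  # perceptually uniform blue -> yellow
    fill_by: str = "count"  # count | percent | none
    edge_color: str | tuple[str, ...] = "black"
    edge_width: float = 1.2
    edge_linetype: str = "solid"
    set_label: str = "name"  # name | name+size | none
    region_label: str = "both"  # count | percent | both | none
    legend: bool = True
    figure_size: tuple[float, float] = (7.0, 6.0)
    background: str = "white"
    layers: tuple[int, ...] = (1, 2, 3, 4)
    font_size: float = 11.0  # figure-relative minimum readable size
    region_font_size: float = 9.0

    def __post_init__(self) -> None:
        if self.fill_by not in ("count", "percent", "none"):
            raise StyleError(f"fill_by must be count|percent|none, got {self.fill_by!r}")
        if self.set_label not in ("name", "name+size", "none"):
            raise StyleError(f"set_label must be name|name+size|none, got {self.set_label!r}")
        if self.region_label not in ("count", "percent", "both", "none"):
            raise StyleError(
                f"region_label must be count|percent|both|none, got {self.region_label!r}")
        if any(l not in (1, 2, 3, 4) for l in self.layers):
            raise StyleError(f"layers must be within 1..4, got {self.layers}")

    @classmethod
    def from_dict(cls, options: dict) -> "StyleConfig":
        known = {f.name for f in fields(cls)}
        unknown = sorted(set(options) - known)
        if unknown:
            raise StyleError(f"unknown style option(s): {unknown}; known: {sorted(known)}")
        opts = dict(options)
        for key in ("figure_size", "layers", "edge_color"):
            if key in opts and isinstance(opts[key], list):
                opts[key] = tuple(opts[key])
        return cls(**opts)


def layer_toggle(style: StyleConfig, layer: int, on: bool) -> StyleConfig:
    """Enable or disable one of the four layers; toggling twice restores
    the original style."""
    if layer not in (1, 2, 3, 4):
        raise StyleError(f"layer must be 1..4, got {layer}")
    layers = set(style.layers)
    (layers.add if on else layers.discard)(layer)
    return replace(style, layers=tuple(sorted(layers)))


def _poly_path(poly) -> MplPath:
    vertices, codes = [], []
    for ring in poly.rings():
        ring = np.asarray(ring)
        vertices.extend(ring)
        codes.extend([MplPath.MOVETO] + [MplPath.LINETO] * (len(ring) - 2)
                     + [MplPath.CLOSEPOLY])
    return MplPath(vertices, codes)


def _edge_colors(style: StyleConfig, n: int) -> list[str]:
    if isinstance(style.edge_color, (list, tuple)):
        if len(style.edge_color) != n:
            raise StyleError(f"{len(style.edge_color)} edge colors for {n} sets")
        return list(style.edge_color)
    return [style.edge_color] * n


_LINESTYLES = {"solid": "-", "dashed": "--", "dotted": ":", "dashdot": "-."}


def render(pd_obj: VennPlotData, style: StyleConfig | None = None) -> Figure:
    """Draw the four-layer Venn figure from plot data.

    Fill values come from region counts (or percents); zero-valued
    regions are filled at the colormap minimum rather than left blank so
    the partition stays visible.  Labels of zero-area regions are
    skipped (they have no interior anchor).
    """
    style = style or StyleConfig()
    if style.fill_by != "none" and not pd_obj.has_values:
        raise VennError("plot data carries no set values; attach a collection "
                        "or use fill_by='none'")
    fig = Figure(figsize=style.figure_size)
    fig.patch.set_facecolor(style.background)
    ax = fig.add_subplot(111)
    ax.set_aspect("equal")
    ax.set_axis_off()

    drawn = []
    # layer 1: region fills mapped to count/percent, with color-bar legend
    if 1 in style.layers:
        cmap = mpl.colormaps[style.colormap]
        if style.fill_by == "none":
            values = None
            norm = None
        else:
            values = [r.count if style.fill_by == "count" else r.percent
                      for r in pd_obj.regions]
            vmin, vmax = min(values), max(values)
            norm = Normalize(vmin=vmin, vmax=vmax if vmax > vmin else vmin + 1)
        for i, region in enumerate(pd_obj.regions):
            if region.poly.is_empty:
                continue
            color = "0.85" if values is None else cmap(norm(values[i]))
            patch = PathPatch(_poly_path(region.poly), facecolor=color,
                              edgecolor="none", zorder=1)
            patch.set_gid(f"region-{region.mask}")
            ax.add_patch(patch)
            drawn.append(patch)
        if style.legend and values is not None:
            sm = mpl.cm.ScalarMappable(norm=norm, cmap=cmap)
            cbar = fig.colorbar(sm, ax=ax, shrink=0.7)
            cbar.set_label(style.fill_by)

    # layer 2: set edges
    if 2 in style.layers:
        colors = _edge_colors(style, pd_obj.n)
        ls = _LINESTYLES.get(style.edge_linetype, style.edge_linetype)
        for edge_datum, color in zip(pd_obj.set_edges, colors):
            v = edge_datum.edge.vertices
            (line,) = ax.plot(v[:, 0], v[:, 1], color=color, lw=style.edge_width,
                              ls=ls, zorder=2)
            line.set_gid(f"edge-{edge_datum.name}")
            drawn.append(line)

    # layer 3: set labels
    if 3 in style.layers and style.set_label != "none":
        for e in pd_obj.set_edges:
            text = e.name
            if style.set_label == "name+size" and pd_obj.has_values:
                text = f"{e.name} ({e.set_size})"
            t = ax.annotate(text, e.label_anchor.as_tuple(), ha="center", va="center",
                            fontsize=style.font_size, zorder=3)
            t.set_gid(f"setlabel-{e.name}")
            drawn.append(t)

    # layer 4: region labels at interior anchors (skipped for empty polygons)
    if 4 in style.layers and style.region_label != "none" and pd_obj.has_values:
        for r in pd_obj.regions:
            if r.label_anchor is None:
                continue
            if style.region_label == "count":
                text = str(r.count)
            elif style.region_label == "percent":
                text = f"{r.percent:.1f}%"
            else:
                text = f"{r.count}\n({r.percent:.1f}%)"
            t = ax.annotate(text, r.label_anchor.as_tuple(), ha="center", va="center",
                            fontsize=style.region_font_size, zorder=4)
            t.set_gid(f"regionlabel-{r.mask}")
            drawn.append(t)

    # frame the drawing even when every layer is off
    xs, ys = [], []
    for e in pd_obj.set_edges:
        xs.extend(e.edge.vertices[:, 0])
        ys.extend(e.edge.vertices[:, 1])
    if xs:
        pad_x = 0.15 * (max(xs) - min(xs) or 1.0)
        pad_y = 0.15 * (max(ys) - min(ys) or 1.0)
        ax.set_xlim(min(xs) - pad_x, max(xs) + pad_x)
        ax.set_ylim(min(ys) - pad_y, max(ys) + pad_y)
    return fig


def export(fig: Figure, path, format: str | None = None, dpi: int = 150) -> Path:
    """Write the figure to SVG/PNG/PDF.

    SVG and PDF are stripped of timestamps (and SVG ids are salted with
    a constant), so repeated exports of the same figure are
    byte-identical.
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt not in _FORMATS:
        raise VennError(f"unknown format {fmt!r}; supported: {', '.join(_FORMATS)}")
    with mpl.rc_context({"svg.hashsalt": _HASHSALT}):
        if fmt == "svg":
            fig.savefig(path, format="svg", metadata={"Date": None})
        elif fmt == "pdf":
            fig.savefig(path, format="pdf",
                        metadata={"CreationDate": None, "ModDate": None})
        else:
            fig.savefig(path, format="png", dpi=dpi)
    return path
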