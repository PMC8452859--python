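"""Polygon primitives, boolean operations, and 2-7-set Venn layouts.

Everything is polygonal: smooth curves are discretized (default 720
vertices per curve) in an abstract [0,1]x[0,1] plot frame with y up.
Boolean operations are delegated to shapely; a thin :class:`PolyShape`
wrapper enforces cleaning (closed, de-duplicated, non-self-intersecting
rings) so that region decomposition is robust.

Layout families
---------------
* *classic* — two/three circles and the frozen four-ellipse
  configuration (congruent 2:1 ellipses at +/-45 degrees).
* *constructive* — an Edwards-style construction valid for n=3..7: a
  half-plane, a perpendicular half-plane, a disc, and for each further
  set a "cogwheel" disc whose boundary is a square wave
  ``rho(theta) = r + h_k * sign(cos(2**(k-3) * theta))`` weaving across
  the disc boundary with ``2**(k-3)`` teeth.  The cosine phase places
  every sign combination of the gear waves inside every quadrant, which
  is what guarantees all ``2**n - 1`` regions are realized.

Validity of a layout is always defined operationally by
:func:`validate_layout`: exactly ``2**n - 1`` positive-area, pairwise
disjoint regions whose areas sum to the union area.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely import affinity
from shapely.geometry import MultiPolygon, Point, Polygon
from shapely.ops import polylabel, unary_union

from .setalgebra import MAX_SETS, MIN_SETS, RegionMask, VennError, all_masks

#: Default number of vertices used to discretize a smooth closed curve.
CURVE_VERTICES = 720
#: Relative area tolerance: slivers below EPS_REL * union_area are empty.
EPS_REL = 1e-6


class GeometryError(ValueError):
    """Invalid geometric input (degenerate primitive, unclean ring...)."""


@dataclass(frozen=True)
class AnchorPoint:
    """A finite planar point anchoring a text label."""

    x: float
    y: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise GeometryError(f"non-finite anchor ({self.x}, {self.y})")

    def as_tuple(self) -> tuple[float, float]:
        return (self.x, self.y)


def _close_ring(ring: np.ndarray) -> np.ndarray:
    """Explicitly close a ring and drop consecutive duplicate vertices."""
    ring = np.asarray(ring, dtype=float)
    if ring.ndim != 2 or ring.shape[1] != 2:
        raise GeometryError("a ring is a sequence of (x, y) vertices")
    keep = [0]
    for i in range(1, len(ring)):
        if not np.allclose(ring[i], ring[keep[-1]]):
            keep.append(i)
    ring = ring[keep]
    if len(ring) and np.allclose(ring[0], ring[-1]):
        ring = ring[:-1]
    if len(ring) < 3:
        raise GeometryError("a ring needs at least 3 distinct vertices")
    return np.vstack([ring, ring[0]])


@dataclass(frozen=True)
class PolyShape:
    """One or more clean polygonal parts, possibly with holes.

    Wraps a shapely (Multi)Polygon.  Construction validates the rings:
    consecutive duplicate vertices are dropped, rings are explicitly
    closed, and self-intersecting rings are rejected rather than
    silently repaired.
    """

    geom: Polygon | MultiPolygon

    @classmethod
    def from_rings(cls, rings: Sequence[np.ndarray], label: str = "shape") -> "PolyShape":
        """Build from closed rings; a ring contained in a previously seen
        exterior becomes that part's hole, otherwise it starts a new part."""
        parts: list[tuple[np.ndarray, list[np.ndarray]]] = []
        for k, raw in enumerate(rings):
            ring = _close_ring(raw)
            if not shapely.LinearRing(ring).is_simple:
                raise GeometryError(f"{label}: ring {k} is self-intersecting")
            poly = Polygon(ring)
            if poly.area <= 0:
                continue  # zero-area ring: cleaned away
            if not poly.is_valid:
                raise GeometryError(f"{label}: ring {k} is self-intersecting")
            placed = False
            for ext, holes in parts:
                if Polygon(ext).contains(poly):
                    holes.append(ring)
                    placed = True
                    break
            if not placed:
                parts.append((ring, []))
        if not parts:
            return cls(Polygon())
        polys = [Polygon(ext, holes) for ext, holes in parts]
        for k, p in enumerate(polys):
            if not p.is_valid:
                raise GeometryError(f"{label}: part {k} is invalid after assembly")
        geom = polys[0] if len(polys) == 1 else MultiPolygon(polys)
        return cls(geom)

    @classmethod
    def from_shapely(cls, geom) -> "PolyShape":
        """Adopt a shapely result, keeping only polygonal content."""
        if geom.is_empty:
            return cls(Polygon())
        if geom.geom_type == "GeometryCollection":
            polys = [g for g in geom.geoms if g.geom_type in ("Polygon", "MultiPolygon")]
            geom = unary_union(polys) if polys else Polygon()
        if geom.geom_type not in ("Polygon", "MultiPolygon"):
            return cls(Polygon())
        return cls(geom)

    @property
    def area(self) -> float:
        return self.geom.area

    @property
    def is_empty(self) -> bool:
        return self.geom.is_empty or self.geom.area == 0.0

    @property
    def parts(self) -> list[Polygon]:
        if self.geom.is_empty:
            return []
        if self.geom.geom_type == "Polygon":
            return [self.geom]
        return list(self.geom.geoms)

    def largest_part(self) -> Polygon | None:
        parts = self.parts
        return max(parts, key=lambda p: p.area) if parts else None

    def rings(self) -> list[np.ndarray]:
        """All rings (exteriors then holes, per part), explicitly closed."""
        out = []
        for p in self.parts:
            out.append(np.asarray(p.exterior.coords))
            out.extend(np.asarray(r.coords) for r in p.interiors)
        return out


@dataclass(frozen=True)
class EdgeLine:
    """A closed polyline tracing one set's boundary."""

    vertices: np.ndarray

    @classmethod
    def from_shape(cls, shape: PolyShape) -> "EdgeLine":
        part = shape.largest_part()
        if part is None:
            raise GeometryError("cannot trace the edge of an empty shape")
        return cls(np.asarray(part.exterior.coords))


@dataclass(frozen=True)
class ShapeLayout:
    """Per-set shapes, boundary polylines, and set-label anchors."""

    n: int
    shapes: tuple[PolyShape, ...]
    edges: tuple[EdgeLine, ...]
    set_label_anchors: tuple[AnchorPoint, ...]
    provenance: str = "custom"

    def __post_init__(self) -> None:
        if not (len(self.shapes) == len(self.edges) == len(self.set_label_anchors) == self.n):
            raise GeometryError("layout arrays must all have length n")


@dataclass(frozen=True)
class RegionGeometry:
    """The polygon (possibly multi-part, possibly empty) of one region."""

    mask: RegionMask
    poly: PolyShape
    area: float


# ---------------------------------------------------------------------------
# primitives


def circle(center: AnchorPoint | tuple[float, float], radius: float,
           n_vertices: int = CURVE_VERTICES) -> PolyShape:
    """Regular ``n_vertices``-gon approximating a circle."""
    if radius <= 0:
        raise GeometryError(f"radius must be positive, got {radius}")
    if n_vertices < 4:
        raise GeometryError("need at least 4 vertices")
    cx, cy = center.as_tuple() if isinstance(center, AnchorPoint) else center
    t = np.linspace(0.0, 2 * np.pi, n_vertices, endpoint=False)
    ring = np.c_[cx + radius * np.cos(t), cy + radius * np.sin(t)]
    return PolyShape.from_rings([ring], label="circle")


def ellipse(center: AnchorPoint | tuple[float, float], semi_axes: tuple[float, float],
            rotation_deg: float = 0.0, n_vertices: int = CURVE_VERTICES) -> PolyShape:
    """Discretized ellipse with semi-axes ``(a, b)`` rotated about its center."""
    a, b = semi_axes
    if a <= 0 or b <= 0:
        raise GeometryError(f"semi-axes must be positive, got {semi_axes}")
    cx, cy = center.as_tuple() if isinstance(center, AnchorPoint) else center
    t = np.linspace(0.0, 2 * np.pi, n_vertices, endpoint=False)
    x, y = a * np.cos(t), b * np.sin(t)
    phi = math.radians(rotation_deg)
    ring = np.c_[cx + x * math.cos(phi) - y * math.sin(phi),
                 cy + x * math.sin(phi) + y * math.cos(phi)]
    return PolyShape.from_rings([ring], label="ellipse")


def triangle(vertices: Sequence[AnchorPoint | tuple[float, float]]) -> PolyShape:
    """Closed triangle from three non-collinear vertices."""
    if len(vertices) != 3:
        raise GeometryError("a triangle needs exactly 3 vertices")
    pts = [(v.as_tuple() if isinstance(v, AnchorPoint) else tuple(v)) for v in vertices]
    (x0, y0), (x1, y1), (x2, y2) = pts
    cross = (x1 - x0) * (y2 - y0) - (y1 - y0) * (x2 - x0)
    scale = max(abs(c) for p in pts for c in p) or 1.0
    if abs(cross) <= 1e-12 * scale * scale:
        raise GeometryError("triangle vertices are collinear")
    return PolyShape.from_rings([np.asarray(pts)], label="triangle")


def rounded_rectangle(center: AnchorPoint | tuple[float, float], width: float,
                      height: float, corner_radius: float,
                      rotation_deg: float = 0.0,
                      n_vertices: int = CURVE_VERTICES) -> PolyShape:
    """Axis-aligned rectangle with quarter-circle corners, then rotated."""
    if corner_radius < 0 or width <= 2 * corner_radius or height <= 2 * corner_radius:
        raise GeometryError(
            f"need width, height > 2*corner_radius >= 0, got "
            f"w={width}, h={height}, r={corner_radius}")
    cx, cy = center.as_tuple() if isinstance(center, AnchorPoint) else center
    hw, hh, r = width / 2, height / 2, corner_radius
    pts: list[tuple[float, float]] = []
    if r == 0:
        pts = [(hw, -hh), (hw, hh), (-hw, hh), (-hw, -hh)]
    else:
        per_corner = max(int(n_vertices // 4), 8)
        corners = [(hw - r, hh - r, 0.0), (-(hw - r), hh - r, 0.5 * np.pi),
                   (-(hw - r), -(hh - r), np.pi), (hw - r, -(hh - r), 1.5 * np.pi)]
        for qx, qy, start in corners:
            t = np.linspace(start, start + 0.5 * np.pi, per_corner)
            pts.extend(zip(qx + r * np.cos(t), qy + r * np.sin(t)))
    ring = np.asarray(pts)
    phi = math.radians(rotation_deg)
    rot = np.array([[math.cos(phi), -math.sin(phi)], [math.sin(phi), math.cos(phi)]])
    ring = ring @ rot.T + np.array([cx, cy])
    return PolyShape.from_rings([ring], label="rounded_rectangle")


# ---------------------------------------------------------------------------
# boolean operations (same names and semantics as the item-set operations)


def _check_clean(shape: PolyShape, side: str) -> None:
    if not shape.geom.is_valid and not shape.geom.is_empty:
        raise GeometryError(f"operand {side!r} has a self-intersecting ring")


def poly_intersect(a: PolyShape, b: PolyShape) -> PolyShape:
    _check_clean(a, "a"), _check_clean(b, "b")
    return PolyShape.from_shapely(a.geom.intersection(b.geom))


def poly_union(a: PolyShape, b: PolyShape) -> PolyShape:
    _check_clean(a, "a"), _check_clean(b, "b")
    return PolyShape.from_shapely(a.geom.union(b.geom))


def poly_difference(a: PolyShape, b: PolyShape) -> PolyShape:
    _check_clean(a, "a"), _check_clean(b, "b")
    return PolyShape.from_shapely(a.geom.difference(b.geom))


# ---------------------------------------------------------------------------
# layouts


def _layout_from_shapes(shapes: Sequence[PolyShape], provenance: str,
                        anchors: Sequence[AnchorPoint] | None = None) -> ShapeLayout:
    n = len(shapes)
    edges = tuple(EdgeLine.from_shape(s) for s in shapes)
    layout = ShapeLayout(n=n, shapes=tuple(shapes), edges=edges,
                         set_label_anchors=tuple(AnchorPoint(0, 0) for _ in shapes),
                         provenance=provenance)
    if anchors is None:
        anchors = tuple(label_position(layout, i) for i in range(n))
    return ShapeLayout(n=n, shapes=tuple(shapes), edges=edges,
                       set_label_anchors=tuple(anchors), provenance=provenance)


def layout_from_shapes(shapes: Sequence[PolyShape],
                       anchors: Sequence[AnchorPoint] | None = None,
                       provenance: str = "custom") -> ShapeLayout:
    """Assemble a layout from per-set shapes; anchors default to
    :func:`label_position` placements."""
    if not MIN_SETS <= len(shapes) <= MAX_SETS:
        raise GeometryError(f"a layout needs {MIN_SETS}-{MAX_SETS} shapes")
    return _layout_from_shapes(shapes, provenance, anchors)


def _classic_shapes(n: int) -> list[PolyShape]:
    if n == 2:
        return [circle((0.38, 0.5), 0.30), circle((0.62, 0.5), 0.30)]
    if n == 3:
        d, r = 0.16, 0.28
        centers = [(0.5 + d * math.cos(math.radians(a)), 0.5 + d * math.sin(math.radians(a)))
                   for a in (90, 210, 330)]
        return [circle(c, r) for c in centers]
    if n == 4:
        return load_shapes_csv(_data_path("classic4_ellipses.csv"))
    raise GeometryError(
        f"the classic family covers 2-4 sets (got n={n}); "
        "use the constructive family for 5-7 sets")


def edwards_layout(n: int) -> ShapeLayout:
    """Edwards-style constructive layout for 3-7 sets in the unit frame."""
    if not 3 <= n <= MAX_SETS:
        raise GeometryError(f"the constructive family covers 3-{MAX_SETS} sets, got n={n}")
    cx = cy = 0.5
    r, h0, shrink = 0.25, 0.11, 0.45
    shapes = [
        PolyShape.from_rings([np.array([(cx, 0), (1, 0), (1, 1), (cx, 1)])]),
        PolyShape.from_rings([np.array([(0, cy), (1, cy), (1, 1), (0, 1)])]),
        circle((cx, cy), r),
    ]
    for k in range(4, n + 1):
        h = h0 * shrink ** (k - 4)
        freq = 2 ** (k - 3)
        m = max(CURVE_VERTICES, 240 * freq)
        t = np.linspace(0.0, 2 * np.pi, m, endpoint=False)
        w = np.sign(np.cos(freq * t))
        w[w == 0] = 1.0
        rho = r + h * w
        shapes.append(PolyShape.from_rings(
            [np.c_[cx + rho * np.cos(t), cy + rho * np.sin(t)]], label=f"gear{k}"))
    return _layout_from_shapes(shapes[:n], provenance="builtin-constructive")


def builtin_layout(n: int, family: str = "classic") -> ShapeLayout:
    """Deterministic built-in layout for ``n`` sets.

    ``classic`` (circles for 2-3 sets, four ellipses for 4) or
    ``constructive`` (Edwards-style, 3-7 sets).
    """
    if not MIN_SETS <= n <= MAX_SETS:
        raise VennError(
            f"unsupported set count: {n} (need {MIN_SETS}-{MAX_SETS}; "
            "for many sets consider an UpSet plot)")
    if family == "classic":
        return _layout_from_shapes(_classic_shapes(n), provenance="builtin-classic")
    if family == "constructive":
        return edwards_layout(n)
    raise GeometryError(f"unknown layout family {family!r}")


def default_layout(n: int) -> ShapeLayout:
    """The layout used when the caller expresses no preference: classic
    up to four sets, Edwards-style beyond."""
    return builtin_layout(n, "classic" if n <= 4 else "constructive")


def six_triangle_layout() -> ShapeLayout:
    """Six-set layout composed of exactly six triangle primitives
    (Carroll's six-triangle Venn configuration, packaged fixture)."""
    shapes = load_shapes_csv(_data_path("triangles6.csv"))
    tris = [triangle(s.largest_part().exterior.coords[:3]) for s in shapes]
    return _layout_from_shapes(tris, provenance="builtin-classic")


def rounded_rectangle_layout() -> ShapeLayout:
    """Four-set layout from four rotated rounded rectangles (packaged
    fixture; same arrangement as the classic four-ellipse layout)."""
    shapes = load_shapes_csv(_data_path("rounded_rect4.csv"))
    return _layout_from_shapes(shapes, provenance="builtin-classic")


# ---------------------------------------------------------------------------
# region decomposition and validation


def compute_regions(layout: ShapeLayout, eps_rel: float = EPS_REL) -> list[RegionGeometry]:
    """Decompose the layout into its ``2**n - 1`` mask regions.

    Region(mask) = intersection of shapes with bit 1 minus union of
    shapes with bit 0.  Computed by successive splitting of the union so
    the results are disjoint by construction; slivers of relative area
    below ``eps_rel`` count as empty but are retained (empty geometry,
    area 0) so the mask sequence is always complete and canonical.
    """
    for i, s in enumerate(layout.shapes):
        _check_clean(s, f"set {i}")
    union = unary_union([s.geom for s in layout.shapes])
    eps = eps_rel * union.area
    pieces: dict[tuple[int, ...], shapely.Geometry] = {(): union}
    for s in layout.shapes:
        nxt: dict[tuple[int, ...], shapely.Geometry] = {}
        for bits, geom in pieces.items():
            nxt[bits + (1,)] = geom.intersection(s.geom)
            nxt[bits + (0,)] = geom.difference(s.geom)
        pieces = nxt
    out = []
    for mask in all_masks(layout.n):
        poly = PolyShape.from_shapely(pieces[mask.bits])
        if poly.area <= eps:
            poly = PolyShape(Polygon())
        out.append(RegionGeometry(mask=mask, poly=poly, area=poly.area))
    return out


@dataclass(frozen=True)
class LayoutReport:
    """Operational validity report for a layout."""

    n: int
    expected_regions: int
    positive_regions: int
    max_pairwise_overlap: float
    area_mismatch: float
    region_areas: dict[str, float]
    valid: bool
    messages: tuple[str, ...] = ()


def validate_layout(layout: ShapeLayout, eps_rel: float = EPS_REL,
                    regions: list[RegionGeometry] | None = None) -> LayoutReport:
    """Check the region-count law: exactly ``2**n - 1`` positive-area,
    pairwise disjoint regions whose areas sum to the union area."""
    if regions is None:
        regions = compute_regions(layout, eps_rel)
    union_area = unary_union([s.geom for s in layout.shapes]).area
    eps = eps_rel * union_area
    areas = {str(r.mask): r.area for r in regions}
    positive = [r for r in regions if r.area > 0]
    # pairwise overlaps, bounding-box prefiltered
    polys = [r.poly.geom for r in positive]
    max_overlap = 0.0
    if len(polys) > 1:
        tree = shapely.STRtree(polys)
        for i, g in enumerate(polys):
            for j in tree.query(g):
                if j > i:
                    inter = g.intersection(polys[j])
                    if not inter.is_empty:
                        max_overlap = max(max_overlap, inter.area)
    mismatch = abs(sum(areas.values()) - union_area)
    msgs = []
    expected = 2 ** layout.n - 1
    if len(positive) != expected:
        missing = [m for m, a in areas.items() if a <= 0]
        msgs.append(f"{len(positive)} positive-area regions, expected {expected}; "
                    f"empty masks: {missing[:8]}{'...' if len(missing) > 8 else ''}")
    if max_overlap >= eps:
        msgs.append(f"regions overlap by up to {max_overlap:g}")
    if mismatch >= eps:
        msgs.append(f"region areas miss the union area by {mismatch:g}")
    return LayoutReport(
        n=layout.n, expected_regions=expected, positive_regions=len(positive),
        max_pairwise_overlap=max_overlap, area_mismatch=mismatch,
        region_areas=areas, valid=not msgs, messages=tuple(msgs))


# ---------------------------------------------------------------------------
# label anchors


def region_label_anchor(poly: PolyShape) -> AnchorPoint | None:
    """Deterministic interior anchor for a region label.

    Uses the pole of inaccessibility (the interior point farthest from
    the boundary) of the largest part, which stays inside crescents and
    other non-convex regions where the centroid may fall outside.
    Returns None for empty regions (the caller skips the label).
    """
    part = poly.largest_part()
    if part is None or part.area == 0:
        return None
    tol = math.sqrt(part.area) / 100
    p = polylabel(part, tolerance=tol)
    if not part.contains(p):  # extremely thin part: fall back to a interior sample
        p = part.representative_point()
    return AnchorPoint(p.x, p.y)


def label_position(layout: ShapeLayout, set_index: int,
                   override: AnchorPoint | None = None) -> AnchorPoint:
    """Default set-label anchor: the shape boundary point farthest from
    the layout centroid, pushed 5% of the layout diameter outward.
    A user-supplied ``override`` passes through unchanged."""
    if not 0 <= set_index < layout.n:
        raise GeometryError(f"set index {set_index} out of range for n={layout.n}")
    if override is not None:
        return override
    union = unary_union([s.geom for s in layout.shapes])
    cx, cy = union.centroid.x, union.centroid.y
    minx, miny, maxx, maxy = union.bounds
    diam = math.hypot(maxx - minx, maxy - miny)
    part = layout.shapes[set_index].largest_part()
    if part is None:
        raise GeometryError(f"set {set_index} has an empty shape")
    coords = np.asarray(part.exterior.coords)
    d = np.hypot(coords[:, 0] - cx, coords[:, 1] - cy)
    far = coords[int(np.argmax(d))]
    direction = far - np.array([cx, cy])
    norm = np.hypot(*direction) or 1.0
    out = far + direction / norm * 0.05 * diam
    return AnchorPoint(float(out[0]), float(out[1]))


# ---------------------------------------------------------------------------
# shapes CSV format (shape_id, ring_id, x, y), the custom-layout exchange
# format; packaged layout fixtures ship in it.


def write_shapes_csv(shapes: Sequence[PolyShape], path) -> None:
    rows = []
    for si, shape in enumerate(shapes):
        for ri, ring in enumerate(shape.rings()):
            for x, y in ring:
                rows.append((si, ri, x, y))
    pd.DataFrame(rows, columns=["shape_id", "ring_id", "x", "y"]).to_csv(path, index=False)


def load_shapes_csv(path) -> list[PolyShape]:
    df = pd.read_csv(path)
    need = {"shape_id", "ring_id", "x", "y"}
    if not need.issubset(df.columns):
        raise GeometryError(f"shapes CSV must have columns {sorted(need)}")
    shapes = []
    for _, shape_df in df.groupby("shape_id", sort=True):
        rings = [ring_df[["x", "y"]].to_numpy()
                 for _, ring_df in shape_df.groupby("ring_id", sort=True)]
        shapes.append(PolyShape.from_rings(rings, label=f"shape {len(shapes)}"))
    return shapes


def custom_layout(path) -> ShapeLayout:
    """Read a layout from a shapes CSV file (one shape per set)."""
    shapes = load_shapes_csv(path)
    return layout_from_shapes(shapes, provenance="custom")


def _data_path(name: str):
    return resources.files("vennkit").joinpath("data", name)
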