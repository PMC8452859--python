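"""Item-level set model behind a Venn diagram.

A Venn diagram over ``n`` named sets partitions the union of their items
into ``2**n - 1`` *regions*, one per nonempty subset of the sets: the
region for subset ``S`` holds exactly the items that belong to every set
in ``S`` and to no set outside it.  This module computes that partition
(members, counts, percentages of the union) with no geometry involved;
the binary :class:`RegionMask` is the join key that later attaches these
values to region polygons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger("vennkit")

#: Supported number of sets.  One set has no overlaps to show; beyond
#: seven, region geometry becomes unreadable and an UpSet plot is the
#: appropriate visualization.
MIN_SETS = 2
MAX_SETS = 7


class VennError(ValueError):
    """Invalid Venn input (set count, names, masks, selectors)."""


@dataclass(frozen=True)
class RegionMask:
    """Binary inclusion vector identifying one of the ``2**n - 1`` regions.

    ``bits[i] == 1`` means the region lies inside the *i*-th input set,
    ``0`` means outside it; at least one bit is set.  The canonical
    string form concatenates the bits, e.g. ``"1011"`` for n=4.
    """

    bits: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.bits or any(b not in (0, 1) for b in self.bits):
            raise VennError(f"mask bits must be 0/1, got {self.bits!r}")
        if not any(self.bits):
            raise VennError("the all-zero mask does not name a region")

    @classmethod
    def from_string(cls, s: str) -> "RegionMask":
        if not s or set(s) - {"0", "1"}:
            raise VennError(f"not a binary mask: {s!r}")
        return cls(tuple(int(c) for c in s))

    @property
    def n(self) -> int:
        return len(self.bits)

    @property
    def included(self) -> tuple[int, ...]:
        """Indices of the sets this region lies inside."""
        return tuple(i for i, b in enumerate(self.bits) if b)

    def name(self, set_names: Sequence[str], sep: str = "/") -> str:
        return sep.join(set_names[i] for i in self.included)

    def __str__(self) -> str:
        return "".join(map(str, self.bits))


def all_masks(n: int) -> list[RegionMask]:
    """All nonzero masks of length ``n`` in canonical order.

    Canonical order is ascending number of set bits, ties broken by the
    lexicographic order of the mask string; this keeps single-set
    regions first and the full intersection last, and is stable across
    runs.
    """
    masks = [RegionMask(tuple(int(c) for c in format(v, f"0{n}b")))
             for v in range(1, 2 ** n)]
    masks.sort(key=lambda m: (sum(m.bits), str(m)))
    return masks


@dataclass(frozen=True)
class VennCollection:
    """Ordered, named item sets (2-7 of them), deduplicated on ingest."""

    names: tuple[str, ...]
    sets: tuple[frozenset[str], ...]

    @property
    def n(self) -> int:
        return len(self.names)

    def union(self) -> frozenset[str]:
        out: set[str] = set()
        for s in self.sets:
            out |= s
        return frozenset(out)

    def __getitem__(self, name: str) -> frozenset[str]:
        try:
            return self.sets[self.names.index(name)]
        except ValueError:
            raise KeyError(name) from None


@dataclass(frozen=True)
class RegionMembership:
    """One region's items and statistics.

    ``percent`` is the region count as a share of the union of all sets,
    rounded half-away-from-zero to one decimal (items outside every set
    do not exist for a list input, so the union is the natural total).
    """

    mask: RegionMask
    name: str
    members: frozenset[str]
    count: int
    percent: float


def _clean_items(name: str, items: Iterable[str]) -> frozenset[str]:
    cleaned: list[str] = []
    for it in items:
        it = str(it).strip()
        if it:
            cleaned.append(it)
    uniq = frozenset(cleaned)
    dropped = len(cleaned) - len(uniq)
    if dropped:
        logger.info("set %r: removed %d duplicate item(s)", name, dropped)
    return uniq


def make_venn(
    named_sets: Mapping[str, Iterable[str]] | Sequence[tuple[str, Iterable[str]]],
) -> VennCollection:
    """Build a :class:`VennCollection` from 2-7 named item sets.

    Items are compared case-sensitively after stripping surrounding
    whitespace; duplicates within a set are removed (logged at INFO).
    Input order is preserved and defines mask bit order.
    """
    pairs = list(named_sets.items()) if isinstance(named_sets, Mapping) else list(named_sets)
    if not MIN_SETS <= len(pairs) <= MAX_SETS:
        raise VennError(
            f"unsupported set count: {len(pairs)} (need {MIN_SETS}-{MAX_SETS}; "
            "for many sets consider an UpSet plot instead of a Venn diagram)"
        )
    names = [str(name) for name, _ in pairs]
    if any(not n.strip() for n in names):
        raise VennError("set names must be non-empty")
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise VennError(f"duplicate set name(s): {dupes}")
    sets = tuple(_clean_items(name, items) for name, items in pairs)
    return VennCollection(names=tuple(names), sets=sets)


def region_members(venn: VennCollection, mask: RegionMask | str) -> frozenset[str]:
    """Items in exactly the sets flagged by ``mask`` and no others.

    Computed as the intersection of the included sets minus the union of
    the excluded ones.
    """
    if isinstance(mask, str):
        mask = RegionMask.from_string(mask)
    if mask.n != venn.n:
        raise VennError(f"mask length {mask.n} does not match {venn.n} sets")
    inside = [venn.sets[i] for i, b in enumerate(mask.bits) if b]
    members = set(inside[0])
    for s in inside[1:]:
        members &= s
    for i, b in enumerate(mask.bits):
        if not b:
            members -= venn.sets[i]
    return frozenset(members)


def _round1(value: Decimal) -> float:
    return float(value.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def percent_of_union(count: int, union_size: int) -> float:
    """Percentage ``100*count/union_size`` rounded to one decimal
    (half away from zero); 0.0 for an empty union."""
    if count < 0 or count > union_size:
        raise VennError(f"count {count} outside [0, {union_size}]")
    if union_size == 0:
        return 0.0
    return _round1(Decimal(100) * Decimal(count) / Decimal(union_size))


def format_percent(count: int, union_size: int) -> str:
    """Render a region count as a one-decimal percent label, e.g. ``"25.0%"``."""
    return f"{percent_of_union(count, union_size):.1f}%"


def all_regions(venn: VennCollection, sep: str = "/") -> list[RegionMembership]:
    """Membership of every region, in canonical mask order.

    Returns exactly ``2**n - 1`` entries; each item of the union appears
    in exactly one of them (the regions partition the union).
    """
    union_size = len(venn.union())
    out = []
    for mask in all_masks(venn.n):
        members = region_members(venn, mask)
        out.append(
            RegionMembership(
                mask=mask,
                name=mask.name(venn.names, sep),
                members=members,
                count=len(members),
                percent=percent_of_union(len(members), union_size),
            )
        )
    return out


def set_sizes(venn: VennCollection) -> list[tuple[str, int]]:
    """Post-dedup size of each input set, in input order."""
    return [(name, len(s)) for name, s in zip(venn.names, venn.sets)]
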