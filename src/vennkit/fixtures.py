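"""Seeded synthetic collections with exactly prescribed region counts.

The generator works backwards from the answer: for each region mask it
mints fresh, globally unique items and inserts them into exactly the
sets the mask flags.  The resulting collection's region decomposition
must therefore reproduce the prescribed counts, which makes these
fixtures a ground-truth oracle for the whole pipeline.  Item names embed
their mask ("g101_0") so any misclassification is self-diagnosing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .setalgebra import MAX_SETS, MIN_SETS, VennCollection, VennError, all_masks, make_venn


@dataclass(frozen=True)
class FixtureSpec:
    """Prescription for a synthetic collection: one count per region."""

    n: int
    counts: dict[str, int]
    seed: int = 0
    item_prefix: str = "g"

    def __post_init__(self) -> None:
        if not MIN_SETS <= self.n <= MAX_SETS:
            raise VennError(f"n must be {MIN_SETS}-{MAX_SETS}, got {self.n}")
        valid = {str(m) for m in all_masks(self.n)}
        unknown = sorted(set(self.counts) - valid)
        if unknown:
            raise VennError(f"counts given for non-region masks: {unknown}")
        if any(c < 0 for c in self.counts.values()):
            raise VennError("counts must be nonnegative")

    def full_counts(self) -> dict[str, int]:
        """Counts for every mask, absent masks filled with 0, canonical order."""
        return {str(m): int(self.counts.get(str(m), 0)) for m in all_masks(self.n)}

    def to_json(self) -> str:
        return json.dumps({"n": self.n, "counts": self.full_counts(),
                           "seed": self.seed, "item_prefix": self.item_prefix})

    @classmethod
    def from_json(cls, text: str | Path) -> "FixtureSpec":
        if isinstance(text, Path):
            text = text.read_text(encoding="utf-8")
        d = json.loads(text)
        return cls(n=d["n"], counts=d["counts"], seed=d.get("seed", 0),
                   item_prefix=d.get("item_prefix", "g"))


def generate(spec: FixtureSpec) -> VennCollection:
    """Mint items per region and assemble the collection.

    For mask ``m`` with count ``c``, items ``<prefix><m>_0 ...
    <prefix><m>_{c-1}`` are added to exactly the sets flagged by ``m``.
    Deterministic: the same spec always yields the same collection.
    """
    names = [chr(ord("A") + i) for i in range(spec.n)]
    sets: dict[str, list[str]] = {name: [] for name in names}
    for mask in all_masks(spec.n):
        c = spec.counts.get(str(mask), 0)
        for i in range(c):
            item = f"{spec.item_prefix}{mask}_{i}"
            for idx in mask.included:
                sets[names[idx]].append(item)
    return make_venn(list(sets.items()))


def random_spec(n: int, total_items: int, seed: int,
                item_prefix: str = "g") -> FixtureSpec:
    """Multinomial allocation of ``total_items`` across the ``2**n - 1``
    regions (uniform region probabilities), seeded."""
    if total_items < 0:
        raise VennError("total_items must be nonnegative")
    masks = [str(m) for m in all_masks(n)]
    rng = np.random.default_rng(seed)
    alloc = rng.multinomial(total_items, np.full(len(masks), 1.0 / len(masks)))
    return FixtureSpec(n=n, counts={m: int(c) for m, c in zip(masks, alloc)},
                       seed=seed, item_prefix=item_prefix)
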