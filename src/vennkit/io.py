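"""Readers for set inputs.

Three plain-text input modes, all yielding a
:class:`~vennkit.setalgebra.VennCollection`:

* ``per-file`` — one item per line per file; the set name defaults to
  the file stem;
* ``membership-tsv`` — a two-column TSV ``set_name<TAB>item``, grouped
  by the first column (set order = order of first appearance);
* ``json`` — a JSON object mapping set name to an item array.

Items are opaque strings (gene IDs, compounds, species...); blank lines
are skipped, whitespace is stripped, and in-set duplicates are removed
with a logged count.  Empty sets are kept with a warning.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .setalgebra import VennCollection, VennError, make_venn

logger = logging.getLogger("vennkit")

MODES = ("per-file", "membership-tsv", "json")


@dataclass(frozen=True)
class InputSpec:
    """How to read the input sets."""

    mode: str
    paths: tuple[str, ...]
    names: tuple[str, ...] | None = None  # overrides for per-file mode
    lowercase: bool = False

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise VennError(f"unknown input mode {self.mode!r}; use one of {MODES}")
        if not self.paths:
            raise VennError("no input paths given")


def _norm(item: str, lowercase: bool) -> str:
    item = item.strip()
    return item.lower() if lowercase else item


def _read_lines(path: Path, lowercase: bool) -> list[str]:
    try:
        text = path.read_text(encoding="utf-8")
    except OSError as exc:
        raise VennError(f"cannot read {path}: {exc}") from exc
    return [_norm(line, lowercase) for line in text.splitlines() if line.strip()]


def read_sets(spec: InputSpec) -> VennCollection:
    """Read the input sets described by ``spec``."""
    if spec.mode == "per-file":
        pairs = []
        for i, p in enumerate(spec.paths):
            path = Path(p)
            name = spec.names[i] if spec.names and i < len(spec.names) else path.stem
            pairs.append((name, _read_lines(path, spec.lowercase)))
    elif spec.mode == "membership-tsv":
        pairs_map: dict[str, list[str]] = {}
        for p in spec.paths:
            for lineno, line in enumerate(Path(p).read_text(encoding="utf-8").splitlines(), 1):
                if not line.strip():
                    continue
                cols = line.split("\t")
                if len(cols) < 2:
                    raise VennError(f"{p}:{lineno}: expected two tab-separated "
                                    f"columns (set_name, item)")
                name, item = cols[0].strip(), _norm(cols[1], spec.lowercase)
                pairs_map.setdefault(name, [])
                if item:
                    pairs_map[name].append(item)
        pairs = list(pairs_map.items())
    else:  # json
        pairs = []
        for p in spec.paths:
            try:
                data = json.loads(Path(p).read_text(encoding="utf-8"))
            except (OSError, json.JSONDecodeError) as exc:
                raise VennError(f"cannot read JSON {p}: {exc}") from exc
            if not isinstance(data, dict):
                raise VennError(f"{p}: JSON input must map set name -> item array")
            for name, items in data.items():
                if not isinstance(items, list):
                    raise VennError(f"{p}: value of {name!r} is not an array")
                pairs.append((name, [_norm(str(it), spec.lowercase) for it in items]))
    for name, items in pairs:
        if not any(it for it in items):
            logger.warning("set %r is empty", name)
    return make_venn(pairs)


def read_set_files(paths: Sequence[str], names: Sequence[str] | None = None,
                   lowercase: bool = False) -> VennCollection:
    """Convenience wrapper: one plain-text file per set."""
    return read_sets(InputSpec(mode="per-file", paths=tuple(map(str, paths)),
                               names=tuple(names) if names else None,
                               lowercase=lowercase))
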