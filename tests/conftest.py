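"""Shared fixtures and the independent brute-force membership oracle."""

from __future__ import annotations

import numpy as np
import pytest

import vennkit as vk


def brute_force_counts(names, sets):
    """Independent oracle: classify every item of the union directly.

    For each item, build its membership bit-vector by asking each set
    "do you contain it?"; group items by that vector.  No set algebra
    from the package is used.
    """
    regions: dict[str, set[str]] = {}
    union = set().union(*sets) if sets else set()
    for item in union:
        bits = "".join("1" if item in s else "0" for s in sets)
        regions.setdefault(bits, set()).add(item)
    return regions


def random_collection(n, n_items, rng):
    """Random sets over a shared vocabulary (items may be in any subset)."""
    vocab = [f"it{j}" for j in range(n_items)]
    pairs = []
    for i in range(n):
        size = int(rng.integers(0, n_items + 1))
        items = list(rng.choice(vocab, size=size, replace=False)) if size else []
        pairs.append((f"S{i}", items))
    return pairs


@pytest.fixture
def two_sets():
    return vk.make_venn([("A", ["a", "b", "c"]), ("B", ["b", "c", "d"])])


@pytest.fixture
def four_set_plotdata():
    spec = vk.FixtureSpec(n=4, counts={"1111": 2, "1000": 5, "0100": 3, "0010": 1,
                                       "0001": 4, "1100": 2, "0011": 1}, seed=7)
    venn = vk.generate(spec)
    return vk.build_plot_data(venn, vk.builtin_layout(4, "classic"))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
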