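"""Shared fixtures and deliberately naive oracle implementations.

The oracles here recompute each statistic by the most literal method
available (per-base bitmaps, all-pairs gap scans, exhaustive clade
enumeration) so the fast implementations can be checked against them on
random instances. They share no code with the package internals.
"""

from __future__ import annotations

import random

import pytest

from cladescape import SupportTree, TERecord
from cladescape.lineage_clusters import GenusAssignment


# ---------------------------------------------------------------------------
# oracles


def bitmap_covered_bp(records: list[TERecord]) -> int:
    """Occupied bp as the size of an explicit per-base set union."""
    covered: dict[str, set[int]] = {}
    for rec in records:
        covered.setdefault(rec.scaffold_id, set()).update(range(rec.start, rec.end))
    return sum(len(bases) for bases in covered.values())


def allpairs_isolation(records: list[TERecord], clade: str, radius: int):
    """Isolation fraction by checking every same-clade pair's edge gap."""
    recs = [r for r in records if r.clade == clade]
    if not recs:
        return None
    n_isolated = 0
    for i, a in enumerate(recs):
        isolated = True
        for j, b in enumerate(recs):
            if i == j or a.scaffold_id != b.scaffold_id:
                continue
            earlier, later = (a, b) if a.start <= b.start else (b, a)
            if max(0, later.start - earlier.end) <= radius:
                isolated = False
                break
        if isolated:
            n_isolated += 1
    return n_isolated / len(recs)


def exhaustive_single_genus_partition(
    tree: SupportTree, genera: GenusAssignment
) -> set[frozenset[str]]:
    """Enumerate every clade, keep single-genus ones, take set-maximal
    elements. In a tree, maximal single-genus clades are pairwise disjoint
    and (leaves being clades) cover all tips."""
    clades: list[frozenset[str]] = []
    for node in tree.tree.preorder_node_iter():
        tips = frozenset(leaf.taxon.label for leaf in node.leaf_iter())
        if len({genera.genus_of(t) for t in tips}) == 1:
            clades.append(tips)
    maximal = {
        c for c in clades if not any(c < other for other in clades)
    }
    return maximal


# ---------------------------------------------------------------------------
# random instance generators (plain `random`, independent of numpy streams)


def random_records(
    rng: random.Random,
    n: int,
    n_scaffolds: int = 3,
    scaffold_length: int = 200_000,
    clades: tuple[str, ...] = ("sire", "oryco"),
    max_length: int = 5_000,
) -> list[TERecord]:
    records = []
    for i in range(n):
        start = rng.randrange(0, scaffold_length - max_length)
        records.append(
            TERecord(
                scaffold_id=f"sc{rng.randrange(n_scaffolds)}",
                start=start,
                end=start + rng.randrange(1, max_length),
                clade=rng.choice(clades),
                source_id=f"r{i}",
            )
        )
    return records


def random_support_newick(
    rng: random.Random,
    n_tips: int,
    n_genera: int = 4,
    p_absent_support: float = 0.2,
) -> str:
    """A random rooted binary topology over genus-prefixed tip labels, with
    random supports in [0, 1] (some absent) on internal nodes."""
    genera = [chr(ord("A") + i) for i in range(n_genera)]
    labels = [f"{rng.choice(genera)}_{i}" for i in range(n_tips)]

    def build(subset: list[str]) -> str:
        if len(subset) == 1:
            return subset[0]
        k = rng.randrange(1, len(subset))
        left, right = subset[:k], subset[k:]
        support = (
            "" if rng.random() < p_absent_support else format(rng.random(), ".3f")
        )
        return f"({build(left)},{build(right)}){support}"

    rng.shuffle(labels)
    return build(labels) + ";"


@pytest.fixture
def rng() -> random.Random:
    return random.Random(20_240_901)
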