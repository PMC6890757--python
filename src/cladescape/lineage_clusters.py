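"""Genus-specific multiplication analysis on support-annotated gene trees.

Pipeline: (1) collapse every internal node whose support is at or below a
trust threshold (default 0.5, i.e. only clades with bootstrap support > 50%
are believed) into a polytomy; (2) partition the tips into *single-genus
clusters* — maximal clades of the collapsed tree whose tips all belong to one
genus; (3) summarize, per genus, how many tips sit in clusters of size >= 2
(genes multiplied within the genus) and of size >= 8 (heavily multiplied).

A tip in no multi-tip single-genus clade is its own singleton cluster, so the
clusters always partition the tip set. Trees are analyzed as rooted exactly
as read; no re-rooting is attempted, and an absent support is treated as
below any positive threshold.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field

from .core_io import SupportTree

__all__ = [
    "DEFAULT_GENUS_PATTERN",
    "GenusAssignment",
    "GenusClusterSummary",
    "collapse_low_support",
    "single_genus_clusters",
    "multiplication_summary",
    "analyze_tree",
]

DEFAULT_GENUS_PATTERN = r"^([A-Za-z]+)"


@dataclass(frozen=True)
class GenusAssignment:
    """Maps every tip label to its genus."""

    mapping: dict[str, str]

    def __post_init__(self) -> None:
        if not self.mapping:
            raise ValueError("genus assignment is empty")
        if any(not g for g in self.mapping.values()):
            raise ValueError("every tip must map to a nonempty genus")

    @classmethod
    def from_labels(
        cls,
        labels: list[str],
        pattern: str = DEFAULT_GENUS_PATTERN,
    ) -> "GenusAssignment":
        """Extract genera from tip labels with a one-group regex (default:
        the leading alphabetic token, e.g. "Tc_00123" -> "Tc")."""
        compiled = re.compile(pattern)
        mapping: dict[str, str] = {}
        for label in labels:
            match = compiled.search(label)
            if match is None or not match.group(1):
                raise ValueError(
                    f"tip label {label!r} does not match genus pattern {pattern!r}"
                )
            mapping[label] = match.group(1)
        return cls(mapping)

    def genus_of(self, label: str) -> str:
        return self.mapping[label]

    @property
    def genera(self) -> list[str]:
        return sorted(set(self.mapping.values()))


@dataclass
class GenusClusterSummary:
    """Cluster-size histogram and multiplied fractions for one genus."""

    genus: str
    histogram: Counter = field(default_factory=Counter)  # cluster size -> count
    n_tips: int = 0

    def __post_init__(self) -> None:
        total = sum(size * count for size, count in self.histogram.items())
        if total != self.n_tips:
            raise ValueError(
                f"histogram accounts for {total} tips but n_tips={self.n_tips}"
            )

    def _fraction_at_least(self, min_size: int) -> float:
        if self.n_tips == 0:
            return 0.0
        tips = sum(
            size * count for size, count in self.histogram.items() if size >= min_size
        )
        return tips / self.n_tips

    @property
    def fraction_multiplied(self) -> float:
        """Fraction of the genus's tips in clusters of size >= 2."""
        return self._fraction_at_least(2)

    @property
    def fraction_ge8(self) -> float:
        """Fraction of the genus's tips in clusters of size >= 8."""
        return self._fraction_at_least(8)


def collapse_low_support(tree: SupportTree, threshold: float = 0.5) -> SupportTree:
    """Collapse internal nodes with support <= threshold (or absent).

    Each untrusted node is deleted and its children attach to its parent,
    forming a polytomy. Tips and the root are never collapsed. The input tree
    is left untouched. Support exactly at the threshold collapses ("greater
    than" is the trust rule).
    """
    if not (0.0 <= threshold <= 1.0):
        raise ValueError("threshold must be in [0, 1]")
    out = tree.clone()
    root = out.tree.seed_node
    doomed = [
        node
        for node in out.tree.postorder_node_iter()
        if node is not root
        and not node.is_leaf()
        and (node.support is None or node.support <= threshold)
    ]
    for node in doomed:
        node.edge.collapse()
    return out


def single_genus_clusters(
    tree: SupportTree,
    genera: GenusAssignment,
) -> list[frozenset[str]]:
    """Partition tips into maximal single-genus clades of a (collapsed) tree.

    Walk from the root: a node all of whose tips share one genus is emitted
    as a cluster and not descended into (maximality); otherwise recurse. A
    leaf is trivially single-genus, so tips outside any multi-tip cluster
    come out as singletons and the result is always a partition.
    """
    for label in tree.tip_labels:
        if label not in genera.mapping:
            raise ValueError(f"tip {label!r} has no genus assignment")

    clusters: list[frozenset[str]] = []

    def genera_under(node) -> set[str]:
        return {
            genera.genus_of(leaf.taxon.label) for leaf in node.leaf_iter()
        }

    def walk(node) -> None:
        if node.is_leaf() or len(genera_under(node)) == 1:
            clusters.append(
                frozenset(leaf.taxon.label for leaf in node.leaf_iter())
            )
            return
        for child in node.child_nodes():
            walk(child)

    walk(tree.tree.seed_node)
    return clusters


def multiplication_summary(
    clusters: list[frozenset[str]],
    genera: GenusAssignment,
) -> dict[str, GenusClusterSummary]:
    """Per-genus cluster-size histograms and multiplied fractions."""
    seen: set[str] = set()
    histograms: dict[str, Counter] = {g: Counter() for g in genera.genera}
    n_tips: dict[str, int] = {g: 0 for g in genera.genera}
    for cluster in clusters:
        if seen & cluster:
            raise ValueError("clusters are not disjoint")
        seen |= cluster
        cluster_genera = {genera.genus_of(label) for label in cluster}
        if len(cluster_genera) != 1:
            raise ValueError(f"cluster {sorted(cluster)} spans multiple genera")
        genus = cluster_genera.pop()
        histograms[genus][len(cluster)] += 1
        n_tips[genus] += len(cluster)
    return {
        genus: GenusClusterSummary(genus=genus, histogram=histograms[genus], n_tips=n_tips[genus])
        for genus in genera.genera
    }


def analyze_tree(
    tree: SupportTree,
    genera: GenusAssignment | None = None,
    threshold: float = 0.5,
    genus_pattern: str = DEFAULT_GENUS_PATTERN,
) -> dict[str, GenusClusterSummary]:
    """Collapse, cluster and summarize in one call."""
    if genera is None:
        genera = GenusAssignment.from_labels(tree.tip_labels, genus_pattern)
    collapsed = collapse_low_support(tree, threshold)
    clusters = single_genus_clusters(collapsed, genera)
    return multiplication_summary(clusters, genera)
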