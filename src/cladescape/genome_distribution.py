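"""Genomic-landscape statistics: fixed windows, same-clade isolation, and
anchor-gene neighborhood scans.

Windows tile each scaffold from coordinate 0 in non-overlapping steps of
``window_size`` (default 20 kb; the last window may be short). A record
belongs to exactly one window, the one containing its 5'-most internal
coordinate, so per-clade window counts always sum to the number of records.

A record is *isolated* when no other record of the same clade on the same
scaffold lies within ``radius`` bp edge-to-edge (gap = max(0, later.start -
earlier.end); overlap means gap 0; "within" is inclusive, gap <= radius).
Cross-scaffold distances are treated as infinite.

The neighborhood scan reports, for each anchor gene, every other gene whose
interval lies within ``cluster_range`` bp edge-to-edge of the anchor — the
view used to look for metabolic-gene-cluster-style co-localization.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .core_io import GeneRecord, ScaffoldTable, TERecord

__all__ = [
    "DEFAULT_WINDOW_SIZE",
    "WindowProfile",
    "IsolationStats",
    "NeighborhoodHit",
    "window_profile",
    "gc_percent",
    "isolation_fraction",
    "neighborhood_scan",
]

DEFAULT_WINDOW_SIZE = 20_000


def gc_percent(sequence: str) -> float | None:
    """100 * (G+C) / (A+C+G+T); ambiguous bases are excluded from the
    denominator. ``None`` when no unambiguous bases are present."""
    seq = sequence.upper()
    gc = seq.count("G") + seq.count("C")
    at = seq.count("A") + seq.count("T")
    if gc + at == 0:
        return None
    return 100.0 * gc / (gc + at)


@dataclass
class WindowProfile:
    """Per-window clade counts (and %GC when sequences are available)."""

    table: pd.DataFrame  # columns: scaffold, window, start, end, gc, <clade...>
    window_size: int
    clades: list[str]

    def counts(self, clade: str) -> pd.Series:
        return self.table[clade]

    def total_count(self, clade: str) -> int:
        return int(self.table[clade].sum())


def window_profile(
    records: Sequence[TERecord],
    scaffolds: ScaffoldTable,
    window_size: int = DEFAULT_WINDOW_SIZE,
    with_gc: bool = False,
) -> WindowProfile:
    """Count records of each clade in fixed windows along every scaffold."""
    if window_size <= 0:
        raise ValueError("window_size must be positive")
    if with_gc and not scaffolds.has_sequences:
        raise ValueError("with_gc requires FASTA-backed scaffolds (sequences)")
    scaffolds.validate_records(records)

    clades = sorted({rec.clade for rec in records})
    counts: dict[tuple[str, int], dict[str, int]] = {}
    for rec in records:
        key = (rec.scaffold_id, rec.start // window_size)
        counts.setdefault(key, {})
        counts[key][rec.clade] = counts[key].get(rec.clade, 0) + 1

    rows = []
    for scaffold_id in sorted(scaffolds):
        length = scaffolds.length_of(scaffold_id)
        n_windows = (length + window_size - 1) // window_size
        seq = scaffolds.sequence(scaffold_id) if with_gc else None
        for w in range(n_windows):
            start = w * window_size
            end = min(start + window_size, length)
            row: dict = {
                "scaffold": scaffold_id,
                "window": w,
                "start": start,
                "end": end,
                "gc": gc_percent(seq[start:end]) if seq is not None else None,
            }
            per_clade = counts.get((scaffold_id, w), {})
            for clade in clades:
                row[clade] = per_clade.get(clade, 0)
            rows.append(row)
    columns = ["scaffold", "window", "start", "end", "gc", *clades]
    table = pd.DataFrame(rows, columns=columns)
    return WindowProfile(table=table, window_size=window_size, clades=clades)


@dataclass
class IsolationStats:
    """How many records of a clade have no same-clade neighbor in range."""

    clade: str
    radius: int
    n_records: int
    n_isolated: int

    @property
    def fraction_isolated(self) -> float | None:
        """None (undefined) when the clade has no records."""
        if self.n_records == 0:
            return None
        return self.n_isolated / self.n_records


def isolation_fraction(
    records: Iterable[TERecord],
    clade: str,
    radius: int = DEFAULT_WINDOW_SIZE,
) -> IsolationStats:
    """Fraction of a clade's records with no same-clade neighbor within
    ``radius`` bp (edge-to-edge, inclusive) on the same scaffold.

    Sorted sweep: for a record, the nearest following-neighbor gap is set by
    the smallest following start, and the nearest preceding gap by the
    largest preceding end, so one forward and one backward pass with a
    running max-end suffice.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    same_clade = [r for r in records if r.clade == clade]
    n_records = len(same_clade)
    if n_records == 0:
        return IsolationStats(clade=clade, radius=radius, n_records=0, n_isolated=0)

    n_isolated = 0
    by_scaffold: dict[str, list[TERecord]] = {}
    for rec in same_clade:
        by_scaffold.setdefault(rec.scaffold_id, []).append(rec)
    for recs in by_scaffold.values():
        recs.sort(key=lambda r: (r.start, r.end))
        n = len(recs)
        has_neighbor = [False] * n
        # forward: gap to the closest following start
        for i in range(n - 1):
            gap = max(0, recs[i + 1].start - recs[i].end)
            if gap <= radius:
                has_neighbor[i] = True
        # backward: gap to the largest preceding end
        max_end = recs[0].end
        for i in range(1, n):
            gap = max(0, recs[i].start - max_end)
            if gap <= radius:
                has_neighbor[i] = True
            max_end = max(max_end, recs[i].end)
        n_isolated += sum(1 for flag in has_neighbor if not flag)
    return IsolationStats(
        clade=clade, radius=radius, n_records=n_records, n_isolated=n_isolated
    )


@dataclass(frozen=True)
class NeighborhoodHit:
    """One gene found within range of an anchor."""

    gene: GeneRecord
    gap: int  # edge-to-edge bp to the anchor (0 when overlapping)

    @property
    def is_te(self) -> bool:
        return self.gene.is_te


def _edge_gap(a: GeneRecord, b: GeneRecord) -> int:
    if a.start < b.start:
        earlier, later = (a, b)
    else:
        earlier, later = (b, a)
    return max(0, later.start - earlier.end)


def neighborhood_scan(
    genes: Sequence[GeneRecord],
    anchors: Sequence[str],
    cluster_range: int = DEFAULT_WINDOW_SIZE,
) -> dict[str, list[NeighborhoodHit]]:
    """For each anchor gene id, list all other genes within ``cluster_range``
    bp (edge-to-edge, inclusive) on the same scaffold, ordered by coordinate,
    each tagged TE / non-TE via its record."""
    if cluster_range < 0:
        raise ValueError("cluster_range must be >= 0")
    by_id = {g.gene_id: g for g in genes}
    missing = [a for a in anchors if a not in by_id]
    if missing:
        raise KeyError(f"unknown anchor ids: {missing}")

    report: dict[str, list[NeighborhoodHit]] = {}
    for anchor_id in anchors:
        anchor = by_id[anchor_id]
        hits = [
            NeighborhoodHit(gene=g, gap=_edge_gap(anchor, g))
            for g in genes
            if g.gene_id != anchor_id
            and g.scaffold_id == anchor.scaffold_id
            and _edge_gap(anchor, g) <= cluster_range
        ]
        hits.sort(key=lambda h: (h.gene.start, h.gene.end, h.gene.gene_id))
        report[anchor_id] = hits
    return report
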