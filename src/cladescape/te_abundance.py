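"""Per-clade TE abundance ("accumulation") scores and fold enrichments.

The abundance score of a clade is the percentage of genome length occupied by
the set union of that clade's annotated intervals:

    percent(clade) = 100 * occupied_bp(clade) / genome_length

Overlapping annotations are merged within a clade before counting, so a base
covered twice by the same clade counts once; intervals of different clades may
each claim the same base in their own rows. Family rollups (Ty1/Copia,
Ty3/Gypsy, ...) merge the union over all member clades. Fold enrichment
between two genomes is the ratio of the two percentages.

Display conventions: percentages round half-up to 2 decimals, fold ratios to
1 decimal; full-precision values are always retained alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from ._rounding import round_half_up
from .core_io import ScaffoldTable, TERecord

__all__ = [
    "Interval",
    "CladeAbundanceTable",
    "merge_intervals",
    "merged_length",
    "abundance_scores",
    "fold_enrichment",
]


@dataclass(frozen=True)
class Interval:
    """A disjoint merged interval, optionally scoped to one clade."""

    scaffold_id: str
    start: int
    end: int
    clade: str | None = None

    @property
    def length(self) -> int:
        return self.end - self.start


def merge_intervals(
    records: Iterable[TERecord],
    scope: str = "per_clade",
) -> list[Interval]:
    """Merge intervals into a sorted, disjoint, non-adjacent set.

    ``scope="per_clade"`` merges within each (scaffold, clade) group and tags
    each output interval with its clade; ``scope="all"`` merges across clades
    per scaffold (the genome-wide "any TE" union). Abutting intervals
    ([100,200) + [200,300)) are joined: they cover a contiguous base run.
    """
    if scope not in ("per_clade", "all"):
        raise ValueError(f"unknown merge scope {scope!r}")
    groups: dict[tuple, list[TERecord]] = {}
    for rec in records:
        key = (rec.scaffold_id, rec.clade) if scope == "per_clade" else (rec.scaffold_id,)
        groups.setdefault(key, []).append(rec)

    merged: list[Interval] = []
    for key in sorted(groups):
        scaffold_id = key[0]
        clade = key[1] if scope == "per_clade" else None
        spans = sorted((r.start, r.end) for r in groups[key])
        cur_start, cur_end = spans[0]
        for start, end in spans[1:]:
            if start <= cur_end:  # overlap or abutting
                cur_end = max(cur_end, end)
            else:
                merged.append(Interval(scaffold_id, cur_start, cur_end, clade))
                cur_start, cur_end = start, end
        merged.append(Interval(scaffold_id, cur_start, cur_end, clade))
    return merged


def merged_length(records: Iterable[TERecord]) -> int:
    """Total bp covered by the set union of the records (across clades)."""
    return sum(iv.length for iv in merge_intervals(records, scope="all"))


@dataclass
class CladeAbundanceTable:
    """Occupied bp and genome percentage per clade, with family rollups."""

    genome_length: int
    occupied_bp: dict[str, int]
    family_of: dict[str, str] = field(default_factory=dict)
    family_occupied_bp: dict[str, int] = field(default_factory=dict)
    total_occupied_bp: int = 0

    def __post_init__(self) -> None:
        if self.genome_length <= 0:
            raise ValueError("genome_length must be positive")
        for clade, bp in self.occupied_bp.items():
            if not (0 <= bp <= self.genome_length):
                raise ValueError(
                    f"occupied bp {bp} for clade {clade!r} outside "
                    f"[0, {self.genome_length}]"
                )

    @classmethod
    def from_percents(
        cls, percents: Mapping[str, float], genome_length: int = 10**9
    ) -> "CladeAbundanceTable":
        """Build a table from already-published percentages (desk checks of
        printed tables, where only the percent is known exactly)."""
        occupied = {
            clade: int(round(genome_length * p / 100.0)) for clade, p in percents.items()
        }
        table = cls(genome_length=genome_length, occupied_bp=occupied)
        table._percent_override = dict(percents)  # type: ignore[attr-defined]
        return table

    @property
    def clades(self) -> list[str]:
        return sorted(self.occupied_bp)

    def percent(self, clade: str) -> float:
        """Full-precision percent of genome occupied by the clade union."""
        override = getattr(self, "_percent_override", None)
        if override is not None and clade in override:
            return float(override[clade])
        return 100.0 * self.occupied_bp[clade] / self.genome_length

    def display_percent(self, clade: str) -> float:
        """Percent as printed: rounded half-up to 2 decimals."""
        return round_half_up(self.percent(clade), 2)

    def family_percent(self, family: str) -> float:
        return 100.0 * self.family_occupied_bp[family] / self.genome_length

    def total_percent(self) -> float:
        return 100.0 * self.total_occupied_bp / self.genome_length


def abundance_scores(
    records: Sequence[TERecord],
    scaffolds: ScaffoldTable,
) -> CladeAbundanceTable:
    """Compute the per-clade abundance table over an annotated genome.

    The denominator is the total scaffold length. The total row and family
    rollups are unions (deduplicated within their scope), so cross-clade
    overlaps never double-count there, while per-clade rows stay additive.
    """
    scaffolds.validate_records(records)
    genome_length = scaffolds.total_length

    occupied: dict[str, int] = {}
    family_of: dict[str, str] = {}
    by_family: dict[str, list[TERecord]] = {}
    for iv in merge_intervals(records, scope="per_clade"):
        assert iv.clade is not None
        occupied[iv.clade] = occupied.get(iv.clade, 0) + iv.length
    for rec in records:
        if rec.family:
            family_of.setdefault(rec.clade, rec.family)
            by_family.setdefault(rec.family, []).append(rec)

    family_occupied = {
        family: merged_length(recs) for family, recs in by_family.items()
    }
    return CladeAbundanceTable(
        genome_length=genome_length,
        occupied_bp=occupied,
        family_of=family_of,
        family_occupied_bp=family_occupied,
        total_occupied_bp=merged_length(records),
    )


def fold_enrichment(
    focal: CladeAbundanceTable,
    reference: CladeAbundanceTable,
    clade: str,
) -> float:
    """Full-precision ratio of the clade's percent in focal vs reference.

    Display the result with :func:`cladescape.round_half_up` at 1 decimal
    (e.g. 11.16 / 0.78 prints as 14.3).
    """
    ref = reference.percent(clade)
    if ref <= 0:
        raise ZeroDivisionError(
            f"reference percent for clade {clade!r} is zero; fold undefined"
        )
    return focal.percent(clade) / ref
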