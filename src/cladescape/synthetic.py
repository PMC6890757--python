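"""Seeded generators emulating every input the pipeline consumes.

Three generators cover the three input families:

* :func:`simulate_te_genome` — scaffold sequences with planted, clade-labeled
  TE intervals (configurable count, length distribution, uniform or clustered
  placement, per-clade GC shift), plus ground truth (occupied bp per clade,
  isolation fractions at a configured radius).
* :func:`simulate_genus_tree` — gene trees made of ortholog-group backbones
  (one tip per genus per group) with planted genus-specific duplication
  clades of controlled size and support, plus per-genus multiplied-fraction
  ground truth.
* :func:`simulate_count_matrix` — Poisson superfamily-by-genus count matrices
  with planted per-genus fold enrichments.

One integer seed drives everything; each generator derives independent
substreams from it (``numpy.random.SeedSequence.spawn``), so adding draws to
one component never perturbs another. Identical (config, seed) pairs produce
byte-identical outputs.

Ground truth is computed by simple independent bookkeeping (all-pairs gap
scans, tip counting), not by calling the pipeline under test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .core_io import ScaffoldTable, SupportTree, SuperfamilyCountMatrix, TERecord
from .core_io import parse_support_tree, write_te_annotations

__all__ = [
    "CladePlan",
    "TEGenomeConfig",
    "GenomeTruth",
    "simulate_te_genome",
    "write_te_genome",
    "DuplicationEvent",
    "TreeSimConfig",
    "TreeTruth",
    "simulate_genus_tree",
    "Enrichment",
    "CountsSimConfig",
    "CountsTruth",
    "simulate_count_matrix",
]

_BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# TE genome


@dataclass(frozen=True)
class CladePlan:
    """How many TEs of one clade to plant and how to place them."""

    clade: str
    count: int
    length_mean: float = 1000.0
    length_sd: float = 0.0
    family: str = ""
    placement: str = "uniform"  # "uniform" | "clustered"
    n_clusters: int = 2
    cluster_spread: float = 2000.0  # sd of offsets around a cluster center, bp
    gc_shift: float = 0.0  # added to the baseline GC fraction inside TE spans

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValueError("count must be >= 0")
        if self.placement not in ("uniform", "clustered"):
            raise ValueError(f"unknown placement {self.placement!r}")
        if self.placement == "clustered" and self.n_clusters < 1:
            raise ValueError("clustered placement needs n_clusters >= 1")


@dataclass(frozen=True)
class TEGenomeConfig:
    """Scaffold layout, base composition and per-clade TE plans."""

    scaffold_lengths: tuple[int, ...]
    clades: tuple[CladePlan, ...]
    gc: float = 0.35
    isolation_radius: int = 20_000
    max_attempts: int = 200  # placement retries per TE before giving up

    def __post_init__(self) -> None:
        if not self.scaffold_lengths or any(l <= 0 for l in self.scaffold_lengths):
            raise ValueError("scaffold lengths must be positive")
        if not (0.0 < self.gc < 1.0):
            raise ValueError("baseline GC must be in (0, 1)")
        for plan in self.clades:
            if not (0.0 < self.gc + plan.gc_shift < 1.0):
                raise ValueError(f"GC shift for clade {plan.clade!r} leaves (0, 1)")


@dataclass
class GenomeTruth:
    """Planted facts about a simulated TE genome."""

    occupied_bp: dict[str, int]
    isolation_fraction: dict[str, float | None]
    isolation_radius: int
    records: list[TERecord] = field(default_factory=list)


def _brute_force_isolation(records: Sequence[TERecord], clade: str, radius: int) -> float | None:
    """All-pairs gap scan; the deliberately naive truth-side computation."""
    recs = [r for r in records if r.clade == clade]
    if not recs:
        return None
    n_isolated = 0
    for a in recs:
        isolated = True
        for b in recs:
            if a is b or a.scaffold_id != b.scaffold_id:
                continue
            earlier, later = (a, b) if a.start <= b.start else (b, a)
            if max(0, later.start - earlier.end) <= radius:
                isolated = False
                break
        if isolated:
            n_isolated += 1
    return n_isolated / len(recs)


def _draw_length(rng: np.random.Generator, plan: CladePlan) -> int:
    if plan.length_sd <= 0:
        return max(1, int(round(plan.length_mean)))
    return max(1, int(round(rng.normal(plan.length_mean, plan.length_sd))))


def _place_clade(
    rng: np.random.Generator,
    plan: CladePlan,
    scaffold_ids: list[str],
    lengths: dict[str, int],
    max_attempts: int,
) -> list[TERecord]:
    """Rejection-sample non-overlapping placements for one clade."""
    placed: dict[str, list[tuple[int, int]]] = {sid: [] for sid in scaffold_ids}
    weights = np.array([lengths[sid] for sid in scaffold_ids], dtype=float)
    weights /= weights.sum()

    centers: list[tuple[str, int]] = []
    if plan.placement == "clustered" and plan.count > 0:
        for _ in range(plan.n_clusters):
            sid = scaffold_ids[rng.choice(len(scaffold_ids), p=weights)]
            centers.append((sid, int(rng.integers(0, lengths[sid]))))

    records: list[TERecord] = []
    for i in range(plan.count):
        te_len = _draw_length(rng, plan)
        for attempt in range(max_attempts):
            if plan.placement == "uniform":
                sid = scaffold_ids[rng.choice(len(scaffold_ids), p=weights)]
                if lengths[sid] < te_len:
                    continue
                start = int(rng.integers(0, lengths[sid] - te_len + 1))
            else:
                sid, center = centers[i % len(centers)]
                if lengths[sid] < te_len:
                    continue
                start = int(round(center + rng.normal(0.0, plan.cluster_spread)))
                start = min(max(start, 0), lengths[sid] - te_len)
            end = start + te_len
            if all(end <= s or start >= e for s, e in placed[sid]):
                placed[sid].append((start, end))
                records.append(
                    TERecord(
                        scaffold_id=sid,
                        start=start,
                        end=end,
                        clade=plan.clade,
                        family=plan.family,
                        source_id=f"{plan.clade}_{i:05d}",
                    )
                )
                break
        else:
            crowded = max(placed, key=lambda sid: len(placed[sid]))
            raise RuntimeError(
                f"could not place TE {i} of clade {plan.clade!r} after "
                f"{max_attempts} attempts (scaffold {crowded} too dense)"
            )
    return records


def simulate_te_genome(
    config: TEGenomeConfig, seed: int
) -> tuple[ScaffoldTable, list[TERecord], GenomeTruth]:
    """Generate scaffolds with planted clade-labeled TE intervals.

    Within a clade, planted intervals never overlap (so the clade's true
    occupied bp is just the sum of lengths); intervals of different clades
    may overlap, exercising downstream merging.
    """
    seq_stream, place_stream = np.random.SeedSequence(seed).spawn(2)
    seq_rng = np.random.default_rng(seq_stream)
    place_rng = np.random.default_rng(place_stream)

    scaffold_ids = [f"sc{i:05d}" for i in range(len(config.scaffold_lengths))]
    lengths = dict(zip(scaffold_ids, config.scaffold_lengths))

    records: list[TERecord] = []
    for plan in config.clades:
        records.extend(
            _place_clade(place_rng, plan, scaffold_ids, lengths, config.max_attempts)
        )
    records.sort(key=lambda r: (r.scaffold_id, r.start, r.end, r.clade))

    # baseline sequence, then rewrite TE spans with shifted GC
    gc_shift_of = {plan.clade: plan.gc_shift for plan in config.clades}
    sequences: dict[str, str] = {}
    for sid in scaffold_ids:
        probs = np.array(
            [(1 - config.gc) / 2, config.gc / 2, config.gc / 2, (1 - config.gc) / 2]
        )
        arr = _BASES[seq_rng.choice(4, size=lengths[sid], p=probs)]
        for rec in records:
            if rec.scaffold_id != sid or gc_shift_of.get(rec.clade, 0.0) == 0.0:
                continue
            gc = config.gc + gc_shift_of[rec.clade]
            p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
            arr[rec.start : rec.end] = _BASES[
                seq_rng.choice(4, size=rec.end - rec.start, p=p)
            ]
        sequences[sid] = "".join(arr)

    scaffolds = ScaffoldTable(lengths, sequences)
    occupied = {}
    for plan in config.clades:
        occupied[plan.clade] = sum(
            r.length for r in records if r.clade == plan.clade
        )
    truth = GenomeTruth(
        occupied_bp=occupied,
        isolation_fraction={
            plan.clade: _brute_force_isolation(
                records, plan.clade, config.isolation_radius
            )
            for plan in config.clades
        },
        isolation_radius=config.isolation_radius,
        records=list(records),
    )
    return scaffolds, records, truth


def write_te_genome(
    scaffolds: ScaffoldTable,
    records: Sequence[TERecord],
    truth: GenomeTruth,
    out_dir: str | Path,
    line_width: int = 80,
) -> dict[str, Path]:
    """Emit FASTA + GFF3 + a truth TSV; returns the written paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fasta = out / "genome.fasta"
    with open(fasta, "w") as handle:
        for sid in sorted(scaffolds):
            handle.write(f">{sid}\n")
            seq = scaffolds.sequence(sid)
            for i in range(0, len(seq), line_width):
                handle.write(seq[i : i + line_width] + "\n")
    gff3 = out / "te_annotations.gff3"
    write_te_annotations(list(records), gff3, format="gff3")
    truth_path = out / "truth.tsv"
    with open(truth_path, "w") as handle:
        handle.write("clade\toccupied_bp\tisolation_fraction\tradius\n")
        for clade in sorted(truth.occupied_bp):
            frac = truth.isolation_fraction.get(clade)
            handle.write(
                f"{clade}\t{truth.occupied_bp[clade]}\t"
                f"{'NA' if frac is None else format(frac, '.6f')}\t"
                f"{truth.isolation_radius}\n"
            )
    return {"fasta": fasta, "gff3": gff3, "truth": truth_path}


# ---------------------------------------------------------------------------
# genus trees


@dataclass(frozen=True)
class DuplicationEvent:
    """One planted genus-specific duplication: a same-genus clade of ``size``
    tips replacing one ortholog-group tip of that genus."""

    genus: str
    size: int

    def __post_init__(self) -> None:
        if self.size < 2:
            raise ValueError("a duplication event needs size >= 2")


@dataclass(frozen=True)
class TreeSimConfig:
    genera: tuple[str, ...]
    n_ortholog_groups: int
    events: tuple[DuplicationEvent, ...] = ()
    event_support: float = 0.95
    backbone_support: float = 0.99
    jitter_fraction: float = 0.0  # fraction of event-root supports pushed low
    jitter_support: float = 0.30

    def __post_init__(self) -> None:
        if not self.genera:
            raise ValueError("need >= 1 genus")
        if len(set(self.genera)) != len(self.genera):
            raise ValueError("duplicate genus labels")
        if self.n_ortholog_groups < 1:
            raise ValueError("need >= 1 ortholog group")
        if not (0.0 <= self.jitter_fraction <= 1.0):
            raise ValueError("jitter_fraction must be in [0, 1]")
        for event in self.events:
            if event.genus not in self.genera:
                raise ValueError(f"event genus {event.genus!r} not in genera")
        per_genus: dict[str, int] = {}
        for event in self.events:
            per_genus[event.genus] = per_genus.get(event.genus, 0) + 1
        for genus, n in per_genus.items():
            if n > self.n_ortholog_groups:
                raise ValueError(
                    f"{n} events for genus {genus!r} exceed "
                    f"{self.n_ortholog_groups} ortholog groups"
                )


@dataclass
class TreeTruth:
    """Planted per-genus multiplied fractions (no-jitter ground truth)."""

    n_tips: dict[str, int]
    fraction_multiplied: dict[str, float]
    fraction_ge8: dict[str, float]
    n_jittered_events: int = 0


def _ladder(parts: list[str], internal_support: float, root_support: float | None) -> str:
    """Left-nesting ladder; innermost internals get ``internal_support``,
    the outermost gets ``root_support`` (omitted when None)."""
    if len(parts) == 1:
        return parts[0]
    cur = parts[0]
    for part in parts[1:-1]:
        cur = f"({cur},{part}){internal_support:g}"
    last = parts[-1]
    label = "" if root_support is None else format(root_support, "g")
    return f"({cur},{last}){label}"


def simulate_genus_tree(
    config: TreeSimConfig, seed: int
) -> tuple[SupportTree, TreeTruth]:
    """Build an ortholog-backbone tree with planted duplication clades.

    The backbone is a ladder of ortholog groups, each group a ladder over the
    genera (one tip per genus), all backbone nodes at ``backbone_support``.
    Each event replaces one group tip of its genus with a same-genus ladder
    clade at ``event_support``; with jitter, a fraction of event *root*
    supports are set to ``jitter_support`` instead (collapsing an event root
    scatters its tips into the surrounding polytomy — inner nodes do not
    change the clade's tip set, so jitter targets roots).
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])

    # which ortholog group hosts each event (distinct per genus)
    events_by_genus: dict[str, list[DuplicationEvent]] = {}
    for event in config.events:
        events_by_genus.setdefault(event.genus, []).append(event)
    host_group: dict[int, dict[str, DuplicationEvent]] = {}
    for genus, events in sorted(events_by_genus.items()):
        groups = rng.choice(config.n_ortholog_groups, size=len(events), replace=False)
        for event, group in zip(events, groups):
            host_group.setdefault(int(group), {})[genus] = event

    n_events = len(config.events)
    n_jitter = int(round(config.jitter_fraction * n_events))
    jittered = set(
        int(i) for i in rng.choice(n_events, size=n_jitter, replace=False)
    ) if n_jitter else set()

    event_index = 0
    group_strings: list[str] = []
    for group in range(config.n_ortholog_groups):
        parts: list[str] = []
        for genus in config.genera:
            tip = f"{genus}_g{group:04d}"
            event = host_group.get(group, {}).get(genus)
            if event is None:
                parts.append(tip)
            else:
                tips = [f"{genus}_g{group:04d}d{j}" for j in range(event.size)]
                root_support = (
                    config.jitter_support
                    if event_index in jittered
                    else config.event_support
                )
                parts.append(_ladder(tips, config.event_support, root_support))
                event_index += 1
        group_strings.append(
            _ladder(parts, config.backbone_support, config.backbone_support)
        )
    newick = _ladder(group_strings, config.backbone_support, None) + ";"
    tree = parse_support_tree(newick)

    # planted bookkeeping (valid for >= 2 genera; a one-genus tree is one
    # single-genus cluster at the root, handled separately)
    n_tips: dict[str, int] = {}
    mult_tips: dict[str, int] = {}
    ge8_tips: dict[str, int] = {}
    for genus in config.genera:
        events = events_by_genus.get(genus, [])
        n = config.n_ortholog_groups - len(events) + sum(e.size for e in events)
        n_tips[genus] = n
        mult_tips[genus] = sum(e.size for e in events)
        ge8_tips[genus] = sum(e.size for e in events if e.size >= 8)
    if len(config.genera) == 1:
        genus = config.genera[0]
        total = n_tips[genus]
        mult_tips[genus] = total if total >= 2 else 0
        ge8_tips[genus] = total if total >= 8 else 0
    truth = TreeTruth(
        n_tips=n_tips,
        fraction_multiplied={
            g: (mult_tips[g] / n_tips[g]) if n_tips[g] else 0.0 for g in config.genera
        },
        fraction_ge8={
            g: (ge8_tips[g] / n_tips[g]) if n_tips[g] else 0.0 for g in config.genera
        },
        n_jittered_events=n_jitter,
    )
    return tree, truth


# ---------------------------------------------------------------------------
# count matrices


@dataclass(frozen=True)
class Enrichment:
    """A planted fold enrichment of one superfamily in one genus."""

    superfamily_index: int
    genus: str
    fold: float

    def __post_init__(self) -> None:
        if self.fold <= 0:
            raise ValueError("fold must be positive")


@dataclass(frozen=True)
class CountsSimConfig:
    genera: tuple[str, ...]
    n_superfamilies: int
    baseline_rate: float = 20.0
    enrichments: tuple[Enrichment, ...] = ()

    def __post_init__(self) -> None:
        if len(self.genera) < 2:
            raise ValueError("need >= 2 genera")
        if self.n_superfamilies < 1:
            raise ValueError("need >= 1 superfamily")
        if self.baseline_rate <= 0:
            raise ValueError("baseline rate must be positive")
        for enr in self.enrichments:
            if enr.genus not in self.genera:
                raise ValueError(f"enrichment genus {enr.genus!r} not in genera")
            if not (0 <= enr.superfamily_index < self.n_superfamilies):
                raise ValueError("enrichment superfamily index out of range")


@dataclass
class CountsTruth:
    """Which (superfamily id, genus) pairs carry a planted fold != 1."""

    enriched: set[tuple[str, str]]
    folds: dict[tuple[str, str], float]


def _superfamily_id(index: int) -> str:
    return f"SIM{index:05d}"


def simulate_count_matrix(
    config: CountsSimConfig, seed: int
) -> tuple[SuperfamilyCountMatrix, CountsTruth]:
    """Draw Poisson counts at the baseline rate, scaled by planted folds."""
    import pandas as pd

    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    fold_of: dict[tuple[int, str], float] = {
        (e.superfamily_index, e.genus): e.fold for e in config.enrichments
    }
    rows = []
    ids = [_superfamily_id(i) for i in range(config.n_superfamilies)]
    for i in range(config.n_superfamilies):
        row = {}
        for genus in config.genera:
            rate = config.baseline_rate * fold_of.get((i, genus), 1.0)
            row[genus] = int(rng.poisson(rate))
        rows.append(row)
    counts = pd.DataFrame(rows, index=ids, columns=list(config.genera))
    names = {sid: f"simulated superfamily {i}" for i, sid in enumerate(ids)}
    truth = CountsTruth(
        enriched={
            (_superfamily_id(e.superfamily_index), e.genus)
            for e in config.enrichments
            if e.fold != 1.0
        },
        folds={
            (_superfamily_id(e.superfamily_index), e.genus): e.fold
            for e in config.enrichments
        },
    )
    return SuperfamilyCountMatrix(counts, names), truth
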