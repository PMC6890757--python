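# Methods

This note documents the models, conventions and numerical choices behind
cladescape, and what the synthetic-data tests do and do not establish.

## Coordinates and formats

All in-memory intervals are 0-based half-open, so `length = end - start`.
GFF3 is converted at the file boundary (1-based inclusive on disk), BED
passes through. Strand is parsed but ignored by every statistic: abundance,
window counts, isolation and neighborhood distances are all strand-blind.
Overlapping same-clade annotations — common when interval calls derive from
overlapping HMM domain hits — are treated as a set union; whether the
upstream annotator deduplicated them does not change any reported quantity.

## Clade abundance

`percent(clade) = 100 · occupied_bp / genome_length`, with `occupied_bp` the
size of the merged union of the clade's intervals and `genome_length` the
total scaffold length of the focal assembly. For external genomes either an
assembly length or a quoted genome size may be supplied as the denominator;
which one is used must be stated when comparing across studies, since they
can differ by several percent. Per-clade rows are independent unions, so a
base annotated to two different clades appears in both rows; the `total` row
and family rollups (Ty1/Copia, Ty3/Gypsy, …) are deduplicated unions over
their member records, and are therefore ≤ the sum of their member rows.

Display: percentages round half-up at 2 decimals, fold ratios at 1 decimal.
Half-up (not banker's) rounding is required to reproduce tie cells such as
4.04503 → 4.05. Full-precision values are retained everywhere; rounding is
display-only, and fold ratios are computed from full-precision percentages.

## Multiplication odds score

`score(Genus, Sig) = log2((N(Genus,Sig) + PS) / (mean_G N(G,Sig) + PS))` with
PS = 5.00 by default (exposed as a parameter). Two conventions are fixed by
recomputing published cells and are load-bearing:

* the mean includes the focal genus (a 98-count row over seven genera scores
  2.059 only under the inclusive mean);
* display values are floored toward −∞ at 2 decimals, not rounded
  (2.0592 → 2.05, −0.17617 → −0.18, 1.42899 → 1.42; rounding would print
  2.06 and fail on a dozen cells).

Ranking of extreme superfamilies uses full-precision scores, with ties broken
lexicographically by superfamily id for determinism. The score has no
zero-sum property across genera; the algebraic identity that *is* testable is
`mean_G 2^score(G) · (mean+PS) = mean(N)+PS`.

A practical floating-point guard: the display floor snaps `score·100` to the
nearest integer when within 1e-9 before flooring, so an exactly-representable
boundary score (e.g. a closed-form 1.00) is never truncated to 0.99 by float
noise. Genuine sub-boundary scores are orders of magnitude farther from the
boundary than 1e-11.

## Single-genus duplication clusters

The trust rule is strict: an internal node survives collapsing only if its
support is *greater than* the threshold (default 0.5); support exactly at the
threshold, and absent support, collapse. Collapsing deletes the node and
attaches its children to its parent (polytomy); tips and the root never
collapse. Support scales are normalized per file: any value > 1 anywhere
marks the whole file percent-scaled (mixed scales in one file are a data
error, not a dialect).

Clusters are the maximal clades of the collapsed tree whose tips share one
genus, found by a root-down walk that stops at the first single-genus node.
Because leaves are single-genus clades, the result is always a partition of
the tips; singletons count in the denominator of `fraction_multiplied`
(tips in clusters of size ≥ 2 over all tips) and `fraction_ge8` (size ≥ 8).
Trees are analyzed as rooted exactly as read — no re-rooting is attempted —
so clusters adjacent to the root depend on the input rooting; callers
comparing trees from different inference runs should root them consistently
first. Genus extraction defaults to the leading alphabetic token of the tip
label (`^([A-Za-z]+)`, e.g. `Tc_00123` → `Tc`) and is fully overridable.

## Landscape statistics

Windows tile each scaffold from coordinate 0 in steps of `window_size`
(default 20,000 bp; the last window may be short). A record is assigned to
the single window containing its start coordinate, so window counts conserve
record totals even when TEs span boundaries. %GC uses unambiguous bases only
(ambiguity codes drop out of the denominator); a window with no unambiguous
bases reports no GC value.

Isolation uses edge-to-edge gaps (`max(0, later.start − earlier.end)`;
overlap = gap 0), inclusive at the radius (gap ≤ radius makes a neighbor),
computed by a sorted sweep (nearest following start, running maximum
preceding end) that the tests check against an all-pairs oracle.
Cross-scaffold distances are infinite, since inter-scaffold gaps in a draft
assembly are unknown. The neighborhood scan applies the same inclusive
edge-to-edge rule around anchor genes, with a 20-kb default matching common
metabolic-gene-cluster search settings.

## Synthetic data

The generators emulate the statistical structure of the three input
families, not their biology:

* **TE genomes** — i.i.d. base composition at a configurable GC fraction,
  TE spans re-drawn with a shifted GC; per-clade interval counts, Gaussian
  lengths, uniform or clustered placement (Gaussian offsets around random
  cluster centers). Placement rejection-samples non-overlap *within* a clade
  (which makes true occupied bp the sum of lengths) while clades may overlap
  each other, exercising the union logic. Infeasible densities fail loudly,
  naming the crowded scaffold.
* **Genus trees** — a ladder backbone of ortholog groups, one tip per genus
  per group, high backbone support; each planted duplication event replaces
  one group tip with a same-genus ladder clade at a planted support. Support
  jitter targets event *root* nodes: collapsing an internal node of a clade
  does not change the clade's tip set, so only root-level jitter can break a
  cluster — which is why recovered multiplied fractions under jitter are
  bounded above by the planted truth rather than scattered around it. With a
  single genus the whole tree is one single-genus cluster, and the truth
  bookkeeping switches to that degenerate case.
* **Count matrices** — independent Poisson cells at a baseline rate
  (default 20), multiplied by planted folds for enriched (superfamily,
  genus) pairs.

One integer seed drives everything through spawned `SeedSequence` substreams,
so outputs are byte-identical across runs and adding draws to one component
cannot perturb another.

What the synthetic tests show: the implementation computes its statistics
correctly (oracle equivalence on random instances) and recovers planted
structure under the stated conditions. What they do not show: behavior on
real annotation pipelines' error modes — nested/fragmented HMM hits, collapsed
repeats in the assembly, misrooted trees, non-Poisson overdispersion of gene
counts. Published figures that depend on the full multi-gigabase assembly
(genome-wide multiplied fractions, the 82–93% isolation figures, raw bp
totals) are therefore backed by arithmetic reproduction of the printed cells
plus these property tests, not by re-running the upstream annotation.

## Problem sizes in the test suite

Tests run on simulated genomes of 0.25–40 Mb with tens of TEs per clade,
trees up to ~60 tips (random-tree oracle checks use ≤ 32 tips × 200 trees),
and count matrices up to 200 superfamilies × 7 genera — sizes chosen so each
oracle comparison is exhaustive and the full suite completes in about a
minute while exercising every code path the assembly-scale inputs would.
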