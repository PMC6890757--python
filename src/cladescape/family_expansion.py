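"""Gene-family multiplication odds scores across plant genera.

For a superfamily signature *Sig* and genus *Genus*, with N(Genus, Sig) the
number of that genus's genes carrying the signature:

    score(Genus, Sig) = log2( (N(Genus, Sig) + PS) / (mean_G N(G, Sig) + PS) )

where the mean runs over ALL genera in the matrix (the focal genus included)
and PS is an additive pseudo-count (default 5.00) that keeps the score finite
when counts are zero. A positive score means the genus carries more copies of
the superfamily than the cross-genus average; all-equal rows score exactly 0.

Display convention: scores are truncated toward -inf at 2 decimals
(2.0592 -> 2.05, -2.3055 -> -2.31), with full precision retained for ranking.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from ._rounding import floor_decimals
from .core_io import SuperfamilyCountMatrix

__all__ = [
    "DEFAULT_PSEUDOCOUNT",
    "multiplication_odds",
    "display_score",
    "OddsScoreTable",
    "score_table",
    "rank_extremes",
]

DEFAULT_PSEUDOCOUNT = 5.0


def multiplication_odds(
    counts: dict[str, int] | pd.Series,
    genus: str,
    ps: float = DEFAULT_PSEUDOCOUNT,
) -> float:
    """Full-precision multiplication odds score for one genus in one row.

    ``counts`` maps every genus (>= 2, focal included) to its gene count.
    """
    if isinstance(counts, pd.Series):
        counts = counts.to_dict()
    if genus not in counts:
        raise KeyError(f"genus {genus!r} not in counts {sorted(counts)}")
    if len(counts) < 2:
        raise ValueError("need counts for >= 2 genera")
    if ps <= 0:
        raise ValueError("pseudo-count must be positive")
    values = list(counts.values())
    if any(v < 0 for v in values):
        raise ValueError("counts must be nonnegative")
    mean = sum(values) / len(values)
    return math.log2((counts[genus] + ps) / (mean + ps))


def display_score(score: float) -> float:
    """Score as printed: floored (truncated toward -inf) at 2 decimals."""
    return floor_decimals(score, 2)


@dataclass
class OddsScoreTable:
    """Full-precision and display odds scores for a whole count matrix."""

    scores: pd.DataFrame  # full precision, superfamilies x genera
    display: pd.DataFrame  # floored at 2 decimals
    counts: pd.DataFrame
    names: dict[str, str]
    ps: float

    @property
    def superfamilies(self) -> list[str]:
        return list(self.scores.index)

    @property
    def genera(self) -> list[str]:
        return list(self.scores.columns)

    def score(self, superfamily: str, genus: str) -> float:
        return float(self.scores.loc[superfamily, genus])

    def display_score(self, superfamily: str, genus: str) -> float:
        return float(self.display.loc[superfamily, genus])


def score_table(
    matrix: SuperfamilyCountMatrix,
    ps: float = DEFAULT_PSEUDOCOUNT,
) -> OddsScoreTable:
    """Score every (superfamily, genus) cell of a count matrix."""
    if ps <= 0:
        raise ValueError("pseudo-count must be positive")
    counts = matrix.counts
    means = counts.mean(axis=1)
    ratios = (counts.add(ps)).div(means + ps, axis=0)
    scores = ratios.apply(lambda col: col.map(math.log2))
    display = scores.apply(lambda col: col.map(lambda s: floor_decimals(s, 2)))
    return OddsScoreTable(
        scores=scores,
        display=display,
        counts=counts.copy(),
        names=dict(matrix.names),
        ps=ps,
    )


def rank_extremes(
    table: OddsScoreTable,
    genus: str,
    n: int,
    direction: str = "top",
) -> list[str]:
    """Superfamilies with the highest ("top") or lowest ("bottom") scores for
    a genus, ordered by full-precision score; ties break lexicographically by
    superfamily id. ``n`` past the table size returns the full ordering."""
    if direction not in ("top", "bottom"):
        raise ValueError(f"direction must be 'top' or 'bottom', got {direction!r}")
    if n < 1:
        raise ValueError("n must be >= 1")
    if genus not in table.genera:
        raise KeyError(f"genus {genus!r} not in table")
    column = table.scores[genus]
    reverse = direction == "top"
    ordered = sorted(
        column.index,
        key=lambda sf: ((-column[sf]) if reverse else column[sf], sf),
    )
    return ordered[:n]
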