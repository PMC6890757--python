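"""Display-rounding conventions used by the reported tables.

Percentages and fold ratios are rounded half-up (0.005 at 2 decimals always
rounds away from zero toward +inf for positive values), matching how the
printed abundance tables behave at ties. Odds scores are *floored* (truncated
toward -inf) at 2 decimals; see :mod:`cladescape.family_expansion`.
"""

from __future__ import annotations

import math
from decimal import ROUND_HALF_UP, Decimal

__all__ = ["round_half_up", "floor_decimals"]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round ``x`` to ``ndigits`` decimals, ties going half-up.

    Python's builtin ``round`` is banker's rounding; the printed tables
    resolve ties upward (e.g. 4.04503 -> 4.05 at 2 decimals).
    """
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(quantum, rounding=ROUND_HALF_UP))


def floor_decimals(x: float, ndigits: int = 2) -> float:
    """Truncate ``x`` toward -inf at ``ndigits`` decimals (2.0592 -> 2.05, -2.3055 -> -2.31)."""
    scale = 10**ndigits
    # Guard against float noise pushing an exactly-representable product
    # below its integer (e.g. 1.13 * 100 == 112.99999...).
    scaled = x * scale
    nearest = round(scaled)
    if math.isclose(scaled, nearest, rel_tol=0.0, abs_tol=1e-9):
        scaled = nearest
    return math.floor(scaled) / scale
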