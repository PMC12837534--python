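"""Small shared helpers."""

from __future__ import annotations

import math
from decimal import ROUND_HALF_UP, Decimal

__all__ = ["round_half_up"]


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero on the decimal value of ``x``.

    Python's built-in ``round`` uses banker's rounding on binary floats;
    reported percentages are formatted half-up to match conventional
    hand-calculated tables (e.g. 51.45 -> 51.5, not 51.4).
    """
    x = float(x)
    if math.isnan(x):
        return x
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))
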