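"""Small shared helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

__all__ = ["round_half_up"]


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero at `ndigits` decimals (37/80 -> 46.3%).

    Python's built-in round is banker's rounding; survey percentages here are
    reported half-up to match conventional reporting.  Goes through Decimal's
    repr-based constructor so 46.25 rounds on its printed value.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))
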