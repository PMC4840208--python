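"""Small shared numeric helpers."""
from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero, as printed tables round.

    Python's builtin round() is banker's rounding; reported percentages in
    this package use conventional half-up rounding instead.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def percent(numerator: float, denominator: float, ndigits: int = 2) -> float:
    """100*numerator/denominator, half-up rounded."""
    if denominator == 0:
        raise ValueError("percent undefined for zero denominator")
    return round_half_up(100.0 * numerator / denominator, ndigits)
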