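"""Decimal round-half-up helpers.

Published screening tables round prevalences to 3 decimals and percentages to
1 decimal with ties going up (0.4705 -> 0.471), which differs from Python's
banker's rounding; all table formatting in this package goes through here.
"""

from decimal import ROUND_HALF_UP, Decimal

__all__ = ["round_half_up", "percent_half_up"]


def round_half_up(value: float, ndigits: int = 0) -> float:
    """Round ``value`` to ``ndigits`` decimals with ties away from zero-ward up."""
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(value))).quantize(quantum, rounding=ROUND_HALF_UP))


def percent_half_up(fraction: float, ndigits: int = 1) -> float:
    """Express a fraction as a percentage rounded half-up to ``ndigits`` decimals."""
    return round_half_up(100.0 * float(fraction), ndigits)
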