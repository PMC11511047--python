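"""Half-up decimal rounding matching the precision of printed tables."""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP

__all__ = ["round_half_up", "pct"]


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round half away from zero at ``ndigits`` decimals (e.g. 0.25 -> 0.3)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def pct(count: int, denominator: int, ndigits: int = 1) -> float:
    """Percentage ``100*count/denominator`` rounded half-up."""
    if denominator <= 0:
        raise ZeroDivisionError("percentage denominator must be positive")
    return round_half_up(100.0 * count / denominator, ndigits)
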