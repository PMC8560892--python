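"""Small shared helpers (presentation rounding)."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero, as statistical packages print (2.675 -> 2.68)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def pct(count: int, total: int, ndigits: int = 1) -> float:
    """Percentage of ``count`` out of ``total``; 0.0 for an empty denominator."""
    if total == 0:
        return 0.0
    return round_half_up(100.0 * count / total, ndigits)
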