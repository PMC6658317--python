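"""Number formatting that matches the reporting conventions of the tables:
percentages to one decimal with half-up rounding, p-values to three decimals
with "<.001" below that.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from typing import Optional


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Round with ties away from zero, on the decimal representation."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def percent(fraction: Optional[float], ndigits: int = 1) -> Optional[float]:
    """A fraction as a percentage rounded half-up to ``ndigits`` decimals."""
    if fraction is None:
        return None
    return round_half_up(100.0 * fraction, ndigits)


def format_percent(fraction: Optional[float], ndigits: int = 1) -> str:
    value = percent(fraction, ndigits)
    if value is None:
        return "NA"
    return f"{value:.{ndigits}f}"


def format_p(p: Optional[float]) -> str:
    """Table-style p-value: three decimals without leading zero, '<.001' floor."""
    if p is None:
        return "(Ref)"
    if p < 0.001:
        return "<.001"
    return f"{p:.3f}".lstrip("0")
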