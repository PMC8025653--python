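"""Significant-figure rounding and formatting for the report layer.

Rounding is half-away-from-zero (the convention of the clinical report
tables), applied only when numbers are rendered; all decisions and
intermediate arithmetic use unrounded values.
"""

from __future__ import annotations

import math
from decimal import ROUND_HALF_UP, Decimal


def sigfig_round(x: float, sig: int = 3) -> float:
    """Round ``x`` to ``sig`` significant figures, halves away from zero."""
    if sig < 1:
        raise ValueError("sig must be >= 1")
    if x == 0 or not math.isfinite(x):
        return float(x)
    d = Decimal(repr(float(x)))
    quantum = Decimal(1).scaleb(d.adjusted() - sig + 1)
    return float(d.copy_abs().quantize(quantum, rounding=ROUND_HALF_UP).copy_sign(d))


def sigfig_str(x: float, sig: int = 3) -> str:
    """Render ``x`` at ``sig`` significant figures with trailing zeros kept.

    Examples: 2 -> "2.00", 92.1902 -> "92.2", 107.0 -> "107", 0.8 -> "0.800".
    """
    if x == 0:
        return f"{0:.{sig - 1}f}"
    if not math.isfinite(x):
        return str(x)
    r = sigfig_round(x, sig)
    exponent = Decimal(repr(r)).adjusted()
    decimals = max(sig - 1 - exponent, 0)
    return f"{r:.{decimals}f}"


def round_half_away(x: float, decimals: int) -> float:
    """Fixed-decimal rounding, halves away from zero (report layer only)."""
    q = Decimal(1).scaleb(-decimals)
    d = Decimal(repr(float(x)))
    return float(d.copy_abs().quantize(q, rounding=ROUND_HALF_UP).copy_sign(d))
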