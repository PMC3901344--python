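"""Small shared numeric helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties going away from zero (37/11 -> 3.4, 4.05 -> 4.1).

    Python's builtin ``round`` is banker's rounding; the printed one-decimal
    table values in this domain use half-up.
    """
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))
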