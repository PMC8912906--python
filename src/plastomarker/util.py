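"""Shared numeric helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int) -> float:
    """Round to ``ndigits`` decimals with ties going away from zero.

    Printed tables use commercial (half-up) rounding; Python's builtin
    ``round`` is half-even, so values like 0.005 would not reproduce.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))
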