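"""Half-up decimal rounding.

Reported F values and correction factors follow the convention of printed
pharmacopoeial tables: round half away from zero at a fixed number of
decimals. Python's built-in ``round`` is banker's rounding, so classification
boundaries (0.60, 1.00) would occasionally flip for ties; all presentation
rounding in this package goes through :func:`round_half_up` instead.
"""

import math
from decimal import ROUND_HALF_UP, Decimal

__all__ = ["round_half_up"]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round ``x`` to ``ndigits`` decimals, ties away from zero.

    Infinities pass through unchanged (an all-aglycone-zero sample has
    F = +inf and stays so after rounding).
    """
    x = float(x)  # accept numpy scalars
    if math.isinf(x):
        return x
    if math.isnan(x):
        raise ValueError("cannot round NaN")
    quantum = Decimal(1).scaleb(-ndigits)
    # repr() gives the shortest decimal string that round-trips the float,
    # so 0.5998 rounds as the user expects rather than as its binary image.
    return float(Decimal(repr(x)).quantize(quantum, rounding=ROUND_HALF_UP))
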