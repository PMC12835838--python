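"""Small shared helpers."""

from __future__ import annotations

import math
from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round half away from zero, the convention used in the published tables.

    Python's built-in ``round`` is banker's rounding; descriptive percentages
    here follow the half-up convention (e.g. 0.25 -> 0.3 at one decimal).
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def ceil_tol(x: float, tol: float = 1e-9) -> int:
    """Ceiling that forgives float noise just above an integer."""
    return int(math.ceil(x - tol))
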