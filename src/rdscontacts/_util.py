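"""Small shared helpers (rounding, percentage formatting)."""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero, as survey tables conventionally do.

    Python's built-in ``round`` uses banker's rounding; reported percentages
    in the survey tables round half up instead (e.g. 0.25 -> 0.3 at 1 digit).
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def percent(count: int, denominator: int, ndigits: int = 1) -> float:
    """Percentage ``100 * count / denominator`` rounded half-up."""
    if denominator <= 0:
        raise ValueError("percentage denominator must be positive")
    return round_half_up(100.0 * count / denominator, ndigits)
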