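"""Small shared helpers: half-up rounding and calendar constants."""

from decimal import Decimal, ROUND_HALF_UP

#: Mean length of a calendar month in days (365.25 / 12).
DAYS_PER_MONTH = 30.4375


def round_half_up(x: float, decimals: int = 0) -> float:
    """Round with ties going away from zero, as in printed clinical tables.

    Python's built-in ``round`` is banker's rounding; report tables in this
    field round 0.5 up, so displayed percentages and odds ratios go through
    this helper.
    """
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def percent(count: int, total: int, decimals: int = 1) -> float:
    """Column percentage with half-up display rounding."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round_half_up(100.0 * count / total, decimals)
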