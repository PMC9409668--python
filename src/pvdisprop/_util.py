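"""Small shared helpers: half-up rounding and percentage formatting."""

from decimal import Decimal, ROUND_HALF_UP


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round ``x`` half-up to ``decimals`` places.

    Python's built-in ``round`` is banker's rounding; report tables in
    pharmacovigilance publications conventionally round half-up, so 27.05
    renders as 27.1, not 27.0.
    """
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def percent(numerator: float, denominator: float, decimals: int = 1) -> float:
    """Percentage of ``numerator`` over ``denominator``, rounded half-up.

    Returns ``nan`` for a zero denominator rather than raising: summary
    tables over empty strata are legal degenerate output.
    """
    if denominator == 0:
        return float("nan")
    return round_half_up(100.0 * numerator / denominator, decimals)
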