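"""Presentation helpers: fractions are canonical internally, percent is formatting only."""

from decimal import ROUND_HALF_UP, Decimal


def round_half_away(x: float, decimals: int = 0) -> float:
    """Round with ties going away from zero (the convention of printed field tables).

    Python's built-in ``round`` uses banker's rounding, which disagrees with how
    forestry tables are typically printed (e.g. 44.5% -> 45%).
    """
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def as_percent(fraction: float, decimals: int = 1) -> float:
    """Convert a proportion in [0, 1] to percent, rounded half away from zero."""
    return round_half_away(100.0 * fraction, decimals)


def fmt(x: float, decimals: int) -> str:
    """Deterministic fixed-decimal string (used for byte-identical CSV output)."""
    return f"{round_half_away(x, decimals):.{decimals}f}"
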