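"""Report-style rounding: round half away from zero at a fixed decimal."""

from decimal import Decimal, ROUND_HALF_UP


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with .5 going away from zero (15.75 -> 15.8, -8.05 -> -8.1)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def pct(fraction: float, ndigits: int = 0) -> float:
    """A fraction as a percent, rounded half-up to ``ndigits`` decimals."""
    return round_half_up(100.0 * fraction, ndigits)
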