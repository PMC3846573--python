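"""Small shared helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Round *value* half-up (commercial rounding) to *ndigits* decimals."""
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(value))).quantize(quantum, rounding=ROUND_HALF_UP))


def pct(numerator, denominator, ndigits: int = 2) -> float:
    """Percentage ``numerator/denominator*100`` rounded half-up.

    The division is carried out in decimal arithmetic so that rounding is
    applied to the true decimal expansion of the ratio, not to a binary
    float approximation.
    """
    if denominator == 0:
        raise ZeroDivisionError("percentage undefined for zero denominator")
    num = Decimal(numerator) if isinstance(numerator, int) else Decimal(repr(numerator))
    den = (
        Decimal(denominator)
        if isinstance(denominator, int)
        else Decimal(repr(denominator))
    )
    frac = num / den * 100
    return float(frac.quantize(Decimal(1).scaleb(-ndigits), rounding=ROUND_HALF_UP))
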