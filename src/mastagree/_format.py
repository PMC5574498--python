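"""Reporting-precision rounding helpers.

Percentages are reported at 1 decimal place and kappa-scale quantities at
2, using half-up rounding (banker's rounding would disagree with published
clinical tables on exact .5 ties).
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(value: float, ndigits: int) -> float:
    """Round *value* to *ndigits* decimals, ties away from zero-half-up."""
    quantum = Decimal(1).scaleb(-ndigits)
    # "+ 0.0" normalizes -0.0 to 0.0 for display
    return float(Decimal(repr(float(value))).quantize(quantum, rounding=ROUND_HALF_UP)) + 0.0


def fmt_pct(value: float | None) -> str:
    """Percent at 1 dp, or 'NA' when undefined."""
    return "NA" if value is None else f"{round_half_up(value, 1):.1f}"


def fmt_kappa(value: float | None) -> str:
    """Kappa-scale value at 2 dp, or 'NA' when undefined."""
    return "NA" if value is None else f"{round_half_up(value, 2):.2f}"
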