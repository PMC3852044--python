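"""Shared numeric/report formatting helpers.

Percentages throughout the pipeline are reported to one decimal place using
a two-stage decimal rounding: the exact percentage is first rounded to two
decimals (half-to-even), then to one decimal with ties resolved toward zero.
This matches the convention of hand-reported comparative-genomics summaries,
where the second decimal is computed first and a trailing 5 is dropped.
"""

from __future__ import annotations

from decimal import ROUND_HALF_DOWN, ROUND_HALF_EVEN, Decimal


def pct1(numerator: float, denominator: float) -> float:
    """``numerator / denominator * 100`` reported to one decimal place.

    Returns 0.0 for a zero denominator (empty-input convention).

    >>> pct1(19, 29)
    65.5
    >>> pct1(3, 8)
    37.5
    """
    if denominator == 0:
        return 0.0
    value = Decimal(str(numerator)) * 100 / Decimal(str(denominator))
    two = value.quantize(Decimal("0.01"), rounding=ROUND_HALF_EVEN)
    one = two.quantize(Decimal("0.1"), rounding=ROUND_HALF_DOWN)
    return float(one)
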