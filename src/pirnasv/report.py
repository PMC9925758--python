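"""Contingency/percentage reporting helpers shared by the CLI summaries."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

__all__ = ["percent", "overlap_percent"]


def percent(numerator: float, denominator: float, digits: int = 1) -> float:
    """100 * numerator / denominator, rounded half-up to ``digits``.

    Half-up rounding matches how published percentages are reported
    (87.5% -> 88 at zero digits), unlike banker's rounding.
    """
    if denominator == 0:
        raise ZeroDivisionError("denominator is zero")
    value = Decimal(100) * Decimal(str(numerator)) / Decimal(str(denominator))
    quant = Decimal(1).scaleb(-digits)
    return float(value.quantize(quant, rounding=ROUND_HALF_UP))


def overlap_percent(n_overlapping: int, n_total: int, digits: int = 1) -> float:
    """Percentage of query elements overlapping a feature set."""
    if n_overlapping > n_total:
        raise ValueError("overlap count exceeds total")
    return percent(n_overlapping, n_total, digits)
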