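"""Small shared helpers."""

from __future__ import annotations

import logging

log = logging.getLogger("holosym")


def round_half_up(x: float, decimals: int = 0) -> float:
    """Round with ties going away from zero (half-up), not banker's rounding.

    Percentages reported by the pipeline ledger use this convention so that
    e.g. 58.5 -> 59 and 96.715 -> 96.72 regardless of float parity.
    """
    import decimal

    q = decimal.Decimal(10) ** -decimals
    d = decimal.Decimal(repr(float(x))).quantize(q, rounding=decimal.ROUND_HALF_UP)
    return float(d)


def percent(numerator: float, denominator: float, decimals: int = 0) -> float:
    """100 * numerator / denominator, half-up rounded to `decimals`."""
    if denominator == 0:
        raise ZeroDivisionError("percent() with zero denominator")
    return round_half_up(100.0 * numerator / denominator, decimals)


def log_filter_step(step: str, n_input: int, n_removed: int) -> None:
    log.info("%s: input=%d removed=%d retained=%d", step, n_input, n_removed, n_input - n_removed)
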