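"""Shared rounding helpers."""

from __future__ import annotations

import math

__all__ = ["round_half_up", "percent"]


def round_half_up(x: float, decimals: int = 0) -> float:
    """Round with ties going up (0.5 -> 1), unlike banker's rounding."""
    factor = 10.0 ** decimals
    value = math.floor(x * factor + 0.5) / factor
    return value if decimals else int(value)


def percent(numerator: float, denominator: float, decimals: int = 0) -> float:
    """A fraction expressed as a rounded percentage (e.g. 610/750 -> 81.3)."""
    if denominator == 0:
        raise ZeroDivisionError("percent with zero denominator")
    return round_half_up(100.0 * numerator / denominator, decimals)
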