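"""Small shared helpers."""

from __future__ import annotations

import math


def round_half_up(x: float) -> int:
    """Round to the nearest integer with exact halves going up.

    Used for all percentages printed by summary operations, so that e.g.
    335/366 reports as 92 (91.53 -> 92) and 27/42 as 64.
    """
    return int(math.floor(x + 0.5))


def percent(numerator: int, denominator: int) -> int:
    """Integer percentage (half-up) of ``numerator / denominator``."""
    if denominator == 0:
        raise ZeroDivisionError("percentage undefined for empty denominator")
    return round_half_up(100.0 * numerator / denominator)
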