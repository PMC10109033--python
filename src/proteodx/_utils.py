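"""Small shared helpers: rounding rule, stage logging."""
from __future__ import annotations

import logging
import math

logger = logging.getLogger("proteodx")


def round_half_up(x: float) -> int:
    """Round to nearest integer with ties going away from zero-half up.

    ``round_half_up(62.5) == 63``; Python's banker's rounding would give 62.
    """
    return int(math.floor(x + 0.5))


def percent(numerator: float, denominator: float) -> int:
    """Integer percentage with the round-half-up rule used in all reports."""
    if denominator == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    return round_half_up(100.0 * numerator / denominator)


def log_stage(stage: str, message: str) -> None:
    """Stage-tagged stderr logging (gene/sample funnel lines)."""
    logger.info("[%s] %s", stage, message)
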