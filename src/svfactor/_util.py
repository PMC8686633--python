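"""Small shared helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_EVEN, Decimal
from zlib import crc32


def percent(count: float, total: float) -> float:
    """100 * count / total, rounded to two decimals with round-half-even.

    All percentages in reports go through this helper so printed values are
    reproducible to the last digit.
    """
    if total == 0:
        raise ZeroDivisionError("percentage of an empty total is undefined")
    raw = Decimal(count) * 100 / Decimal(total)
    return float(raw.quantize(Decimal("0.01"), rounding=ROUND_HALF_EVEN))


def stable_hash(*parts: str) -> int:
    """Deterministic 32-bit hash of string parts, for seeding sub-streams."""
    return crc32("|".join(parts).encode("utf-8"))
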