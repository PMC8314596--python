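"""Shared enumerations and numeric conventions.

The two traits of the bidirectional design are circulating
25-hydroxyvitamin D (``VITD``, analysed on the natural-log nmol/L scale)
and type 2 diabetes (``T2D``, analysed on the log-odds scale).
"""

from __future__ import annotations

import enum

#: Normal quantile used for all 95% confidence intervals and CI->SE
#: reconstruction.  Fixed at 6 decimals (rather than the rounded 1.96) so
#: that every round trip between SEs and CIs is deterministic.
Z_95 = 1.959964


class Trait(str, enum.Enum):
    """Analysis trait: exposure or outcome."""

    T2D = "T2D"
    VITD = "VITD"


class Ancestry(str, enum.Enum):
    SOUTH_ASIAN = "SOUTH_ASIAN"
    EUROPEAN = "EUROPEAN"


class Scale(str, enum.Enum):
    """Scale of a reported effect estimate.

    ``BETA``  -- additive linear-regression slope (ln-nmol/L units here).
    ``LN_OR`` -- natural-log odds ratio (the additive scale for T2D).
    ``OR``    -- odds ratio as printed; converted to ``LN_OR`` on ingest.
    """

    BETA = "BETA"
    LN_OR = "LN_OR"
    OR = "OR"


def direction_sign(direction: str) -> int:
    """Map a direction mark to +1/-1.  Accepts ASCII and typographic minus."""
    if direction in ("+",):
        return 1
    if direction in ("-", "−", "–"):
        return -1
    raise ValueError(f"unrecognised direction mark: {direction!r}")


def sign_direction(x: float) -> str:
    """Direction mark for a signed value; zero maps to '+' (documented tie-break)."""
    return "+" if x >= 0 else "-"
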