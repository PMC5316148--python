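"""Small shared helpers."""

from __future__ import annotations

import math

#: Accepted sex labels throughout the package.
SEXES = ("male", "female")

#: Growth indicators a reference can parametrize.
INDICATORS = ("bmi_for_age", "height_for_age")


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round ``x`` to ``ndigits`` decimals with ties going away from zero.

    Measurements and table cells are conventionally recorded "to the nearest
    0.1" with half-up ties (38.45 -> 38.5), which differs from Python's
    banker's rounding. A tiny epsilon guards against binary representations
    sitting infinitesimally below an exact .x5 boundary.
    """
    scale = 10.0**ndigits
    if x >= 0:
        return math.floor(x * scale + 0.5 + 1e-9) / scale
    return -math.floor(-x * scale + 0.5 + 1e-9) / scale


def truncate(x: float, ndigits: int = 2) -> float:
    """Truncate (not round) ``x`` to ``ndigits`` decimals.

    Used only in the presentation layer for 2x2-table cell percentages,
    where printed tables conventionally cut rather than round so that the
    displayed cells never overshoot 100.
    """
    scale = 10.0**ndigits
    return math.floor(x * scale + 1e-9) / scale


def validate_sex(sex: str) -> str:
    if sex not in SEXES:
        raise ValueError(f"sex must be one of {SEXES}, got {sex!r}")
    return sex
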