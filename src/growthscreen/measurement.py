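"""Duplicate-measurement reconciliation.

Field protocol for weight (and optionally height): measure, reposition,
measure again.  If the two readings agree within tolerance (0.1 kg for
weight), record them; otherwise take a third reading and record the
average of the two closest.  This module encodes that rule exactly,
including the recorded-value rounding to the instrument resolution.

Arithmetic runs in :class:`decimal.Decimal` so that 0.1-resolution inputs
behave as written: the mean of 32.5 and 32.6 is exactly 32.55 and rounds
half-up to 32.6, which binary floats cannot guarantee.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from itertools import combinations

from .errors import ThirdReadingRequired


@dataclass(frozen=True)
class MeasurementSeries:
    """2 or 3 raw readings of one quantity, with the agreement tolerance.

    Readings and tolerance share one unit (kg or cm) at 0.1 resolution.
    """

    readings: tuple
    tolerance: float = 0.1

    def __post_init__(self) -> None:
        if len(self.readings) not in (2, 3):
            raise ValueError(f"expected 2 or 3 readings, got {len(self.readings)}")
        if any(r <= 0 for r in self.readings):
            raise ValueError("readings must be > 0")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")


def _dec(x) -> Decimal:
    return Decimal(str(x))


def _record(value: Decimal) -> float:
    return float(value.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def reconcile(series: MeasurementSeries) -> float:
    """Reduce a series to the recorded value.

    Two readings within tolerance: their mean.  Three readings: the mean
    of the closest pair; when two pairs tie for closest (readings in exact
    arithmetic progression), the mean of all three.  The result is rounded
    half-up to 0.1.  Two readings farther apart than tolerance raise
    :class:`ThirdReadingRequired`.
    """
    rs = [_dec(r) for r in series.readings]
    tol = _dec(series.tolerance)
    if len(rs) == 2:
        if abs(rs[0] - rs[1]) > tol:
            raise ThirdReadingRequired(
                f"readings {series.readings} disagree by more than {series.tolerance}; "
                "take a third reading"
            )
        return _record((rs[0] + rs[1]) / 2)
    pairs = list(combinations(rs, 2))
    gaps = [abs(a - b) for a, b in pairs]
    best = min(gaps)
    closest = [p for p, g in zip(pairs, gaps) if g == best]
    if len(closest) > 1:
        return _record(sum(rs) / 3)
    a, b = closest[0]
    return _record((a + b) / 2)
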