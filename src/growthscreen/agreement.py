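"""Agreement between two binary weight-status classifiers.

The two methods are cross-classified into a 2x2 table with the direct
BMI-for-age method as the reference (columns) and the simplified
screening instrument as the comparator (rows):

              reference unhealthy   reference healthy
  comparator
  unhealthy          a                      b
  healthy            c                      d

Percent agreement is the primary readout:

  overall  = 100 (a + d) / (a + b + c + d)
  positive = 100 a / (a + c)      (agreement on unhealthy, reference margin)
  negative = 100 d / (b + d)      (agreement on healthy, reference margin)

Positive/negative agreement is undefined when its margin is empty and is
reported as such rather than as 0 or 100.  Cohen's kappa is provided as
an optional chance-corrected extra beyond the percent-agreement readout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

from .utils import truncate

_LABELS = ("healthy", "unhealthy")


@dataclass(frozen=True)
class TwoByTwoTable:
    """Counts cross-classifying comparator (rows) against reference (columns).

    a: both unhealthy; b: comparator-unhealthy / reference-healthy;
    c: comparator-healthy / reference-unhealthy; d: both healthy.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in "abcd":
            v = getattr(self, name)
            if not float(v).is_integer() or v < 0:
                raise ValueError(f"count {name} must be a non-negative integer, got {v!r}")
        if self.n < 1:
            raise ValueError("table must contain at least one observation")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def swapped(self) -> "TwoByTwoTable":
        """The same data with the roles of the two methods exchanged (b <-> c)."""
        return TwoByTwoTable(self.a, self.c, self.b, self.d)


@dataclass(frozen=True)
class AgreementReport:
    """Percent-agreement statistics with the counts they came from.

    Unrounded percentages are carried in full precision; ``presentation``
    yields the printed form (integer agreement percentages, cell
    percentages truncated at 2 dp as 2x2 tables are conventionally set).
    ``positive_pct``/``negative_pct`` are None when undefined (empty margin).
    """

    table: TwoByTwoTable
    overall_pct: float
    positive_pct: Optional[float]
    negative_pct: Optional[float]

    @property
    def cell_pct(self) -> dict[str, float]:
        n = self.table.n
        return {k: 100.0 * getattr(self.table, k) / n for k in "abcd"}

    def presentation(self) -> dict:
        fmt = lambda p: None if p is None else int(round(p))
        return {
            "overall": fmt(self.overall_pct),
            "positive": fmt(self.positive_pct),
            "negative": fmt(self.negative_pct),
            "cells": {k: truncate(v, 2) for k, v in self.cell_pct.items()},
        }


def crosstab(pairs: Iterable[tuple[str, str]]) -> TwoByTwoTable:
    """Count (comparator_label, reference_label) pairs into a 2x2 table."""
    a = b = c = d = 0
    n = 0
    for comp, ref in pairs:
        if comp not in _LABELS or ref not in _LABELS:
            raise ValueError(f"labels must be in {_LABELS}, got ({comp!r}, {ref!r})")
        n += 1
        if comp == "unhealthy":
            if ref == "unhealthy":
                a += 1
            else:
                b += 1
        else:
            if ref == "unhealthy":
                c += 1
            else:
                d += 1
    if n == 0:
        raise ValueError("no classification pairs supplied")
    return TwoByTwoTable(a, b, c, d)


def percent_agreement(table: TwoByTwoTable) -> AgreementReport:
    """Overall, positive and negative percent agreement for a 2x2 table."""
    overall = 100.0 * (table.a + table.d) / table.n
    positive = 100.0 * table.a / (table.a + table.c) if table.a + table.c else None
    negative = 100.0 * table.d / (table.b + table.d) if table.b + table.d else None
    return AgreementReport(table, overall, positive, negative)


def cohen_kappa(table: TwoByTwoTable) -> float:
    """Cohen's chance-corrected kappa (optional extra readout).

    kappa = (p_o - p_e) / (1 - p_e) with p_o the observed agreement and
    p_e the agreement expected from the margins.  Degenerate margins
    (p_e = 1) return 1.0 for a perfectly concordant table.
    """
    n = table.n
    p_o = (table.a + table.d) / n
    p_e = ((table.a + table.b) * (table.a + table.c)
           + (table.c + table.d) * (table.b + table.d)) / n**2
    if p_e == 1.0:
        return 1.0 if p_o == 1.0 else 0.0
    return (p_o - p_e) / (1.0 - p_e)


def format_report(report: AgreementReport) -> str:
    """Human-readable report shaped like a published 2x2 comparison table."""
    t, pres = report.table, report.presentation()
    cp = pres["cells"]
    pct = lambda v: "n/a" if v is None else f"{v}%"
    lines = [
        "Weight status comparison (comparator rows vs reference columns)",
        f"{'':>12} {'Unhealthy n (%)':>18} {'Healthy n (%)':>18} {'Total':>10}",
        f"{'Unhealthy':>12} {f'{t.a} ({cp[chr(97)]:.2f})':>18} "
        f"{f'{t.b} ({cp[chr(98)]:.2f})':>18} {t.a + t.b:>10}",
        f"{'Healthy':>12} {f'{t.c} ({cp[chr(99)]:.2f})':>18} "
        f"{f'{t.d} ({cp[chr(100)]:.2f})':>18} {t.c + t.d:>10}",
        f"{'Total':>12} {t.a + t.c:>18} {t.b + t.d:>18} {t.n:>10}",
        f"Overall percent agreement  = 100% x {t.a + t.d}/{t.n} = {pct(pres['overall'])}",
        f"Positive percent agreement = 100% x {t.a}/{t.a + t.c} = {pct(pres['positive'])}",
        f"Negative percent agreement = 100% x {t.d}/{t.b + t.d} = {pct(pres['negative'])}",
    ]
    return "\n".join(lines)
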