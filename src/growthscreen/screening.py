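"""Simplified overweight screening tables ("without BMI calculation" arm).

The instrument is a pair of sex-specific lookup tables.  Rows are
half-year ages from 5.0 to 19.0 years; columns are 11 reference height
percentiles.  Each cell holds the screening weight: the weight at which a
child of that age and column height crosses the +1 SD BMI-for-age cutoff,

    w(a, p) = BMI_{+1SD}(a) * (h_p(a) / 100)^2

with h_p(a) the height-for-age value at percentile p.  Screening needs no
BMI arithmetic: find the age row(s), find the height column(s), and
compare the child's weight to the matched grid cells.  A child whose age
or height falls between rows/columns matches the two bracketing cells in
each direction (up to 4 cells); the decision threshold is the MINIMUM of
the matched cells, so bracketing can only lower the bar — the source of
the instrument's high sensitivity relative to the direct BMI method.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .bmi import ChildRecord, WeightStatus
from .errors import CoverageError, OutOfRangeError, TableInvariantError
from .lms import GrowthReference, value_at_percentile, value_at_zscore
from .utils import round_half_up, validate_sex

#: Default reference height percentiles (columns), low to high.
DEFAULT_PERCENTILES = (1, 3, 5, 15, 25, 50, 75, 85, 95, 97, 99)

#: Default half-year age rows, in years.
DEFAULT_AGE_ROWS = tuple(np.arange(5.0, 19.0 + 1e-9, 0.5))


@dataclass
class ScreeningTable:
    """Per-sex grid of screening weights: half-year age rows x percentile columns.

    ``heights`` and ``weights`` are (n_rows, n_cols) arrays in cm and kg,
    both rendered to 0.1; within every row both must increase strictly
    across columns.
    """

    sex: str
    age_years: np.ndarray
    percentiles: tuple
    heights: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        validate_sex(self.sex)
        self.age_years = np.asarray(self.age_years, dtype=float)
        self.heights = np.asarray(self.heights, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        self.validate()

    def validate(self) -> None:
        n_rows, n_cols = len(self.age_years), len(self.percentiles)
        if self.heights.shape != (n_rows, n_cols) or self.weights.shape != (n_rows, n_cols):
            raise TableInvariantError(
                f"grid shape mismatch: {self.heights.shape} / {self.weights.shape} "
                f"vs {(n_rows, n_cols)}"
            )
        if np.any(np.diff(self.age_years) <= 0):
            raise TableInvariantError("age rows must increase strictly")
        if np.any(self.weights <= 0) or np.any(self.heights <= 0):
            raise TableInvariantError("heights and grid weights must be > 0")
        # Strictly increasing for any realistic reference; ties are tolerated
        # only because 0.1-rendering can collapse columns of a (near-)
        # degenerate reference. A decrease is always a corrupt table.
        for name, grid in (("heights", self.heights), ("weights", self.weights)):
            bad = np.argwhere(np.diff(grid, axis=1) < 0)
            if bad.size:
                r, c = bad[0]
                raise TableInvariantError(
                    f"{name} not increasing in row {self.age_years[r]:g} y "
                    f"between columns {self.percentiles[c]} and {self.percentiles[c + 1]}"
                )

    @property
    def age_span_months(self) -> tuple[int, int]:
        return int(round(self.age_years[0] * 12)), int(round(self.age_years[-1] * 12))


@dataclass(frozen=True)
class GridLookup:
    """The screening cells matched by one child: 1 or 2 age rows x 1 or 2 columns.

    ``cells`` holds (age_row_years, column_percentile, height_cm, weight_kg)
    per matched cell; the effective decision threshold is the minimum of
    the matched grid weights.  ``clamped`` flags a height outside the
    matched rows' column span (nearest edge column used).
    """

    cells: tuple
    clamped: bool

    @property
    def grid_weights(self) -> tuple:
        return tuple(c[3] for c in self.cells)

    @property
    def threshold(self) -> float:
        return min(self.grid_weights)


def build_screening_table(
    bmi_ref: GrowthReference,
    height_ref: GrowthReference,
    sex: str,
    age_years: Sequence[float] = DEFAULT_AGE_ROWS,
    percentiles: Sequence[int] = DEFAULT_PERCENTILES,
) -> ScreeningTable:
    """Construct one sex's screening table from the two LMS references.

    For each age row the column heights are the height-for-age percentile
    values (rendered to 0.1 cm); the screening weight in each cell is the
    +1 SD BMI-for-age cutoff at that row times the squared column height in
    meters, rounded half-up to 0.1 kg.
    """
    validate_sex(sex)
    months = [int(round(a * 12)) for a in age_years]
    missing = []
    for ref in (bmi_ref, height_ref):
        lo, hi = ref.age_range
        missing += [m for m in months if m < lo or m > hi]
    if missing:
        raise CoverageError(
            f"references do not cover months {sorted(set(missing))} needed for the age rows"
        )
    heights = np.empty((len(months), len(percentiles)))
    weights = np.empty_like(heights)
    for i, m in enumerate(months):
        Lh, Mh, Sh = height_ref.lms_at(sex, m)
        bmi_cut = value_at_zscore(1.0, *bmi_ref.lms_at(sex, m))
        for j, p in enumerate(percentiles):
            h = round_half_up(value_at_percentile(p, Lh, Mh, Sh), 1)
            heights[i, j] = h
            weights[i, j] = round_half_up(bmi_cut * (h / 100.0) ** 2, 1)
    return ScreeningTable(sex, np.asarray(age_years, float), tuple(percentiles),
                          heights, weights)


def locate_grid_cells(table: ScreeningTable, age_months: int, height_cm: float) -> GridLookup:
    """Find the screening cell(s) for an age and height.

    The age matches one row when completed-months/12 lies exactly on the
    half-year grid, else the two bracketing rows.  Within each matched row
    the height matches one column when it equals a tabulated height, else
    the two bracketing columns; heights outside the row's span clamp to the
    nearest edge column and the lookup is flagged.
    """
    lo, hi = table.age_span_months
    if age_months < lo or age_months > hi:
        raise OutOfRangeError(
            f"age {age_months} months outside table span "
            f"[{table.age_years[0]:g}, {table.age_years[-1]:g}] years"
        )
    age_y = age_months / 12.0
    below = int(np.searchsorted(table.age_years, age_y + 1e-9) - 1)
    if math.isclose(table.age_years[below], age_y, abs_tol=1e-9):
        rows = [below]
    else:
        rows = [below, below + 1]
    cells = []
    clamped = False
    for r in rows:
        hs = table.heights[r]
        exact = np.flatnonzero(np.isclose(hs, height_cm, atol=1e-9))
        if exact.size:
            cols = [int(exact[0])]
        elif height_cm < hs[0]:
            cols, clamped = [0], True
        elif height_cm > hs[-1]:
            cols, clamped = [len(hs) - 1], True
        else:
            j = int(np.searchsorted(hs, height_cm))
            cols = [j - 1, j]
        for c in cols:
            cells.append((float(table.age_years[r]), table.percentiles[c],
                          float(hs[c]), float(table.weights[r, c])))
    return GridLookup(cells=tuple(cells), clamped=clamped)


def classify_simplified(child: ChildRecord, table: ScreeningTable) -> WeightStatus:
    """Screen a child with the simplified table: no BMI computation.

    Unhealthy when the child's weight reaches ("is placed within") the
    lowest matched grid weight: ``weight >= min(matched cells)``.  Note the
    deliberate asymmetry with the direct BMI arm, which uses a strict
    ``>`` at its cutoff.
    """
    lookup = locate_grid_cells(table, child.age_months, child.height_cm)
    label = "unhealthy" if child.weight_kg >= lookup.threshold - 1e-9 else "healthy"
    return WeightStatus(
        label=label,
        method="simplified",
        detail={
            "weight_kg": child.weight_kg,
            "grid_weights": lookup.grid_weights,
            "threshold": lookup.threshold,
            "cells": lookup.cells,
            "clamped": lookup.clamped,
        },
    )


# ---------------------------------------------------------------------------
# Table round-tripping (delimited text, one block per sex)


def export_table(tables, path) -> None:
    """Write one or more screening tables to a single CSV.

    Layout: one row per (sex, age row); a ``h<p>,w<p>`` column pair per
    percentile, values rendered to 0.1.  Lossless for tables built by
    :func:`build_screening_table` (whose cells are already 0.1-rendered).
    """
    if isinstance(tables, ScreeningTable):
        tables = [tables]
    frames = []
    for t in tables:
        data = {"sex": t.sex, "age_years": t.age_years}
        for j, p in enumerate(t.percentiles):
            data[f"h{p}"] = np.round(t.heights[:, j], 1)
            data[f"w{p}"] = np.round(t.weights[:, j], 1)
        frames.append(pd.DataFrame(data))
    pd.concat(frames).to_csv(path, index=False, float_format="%.1f")


def import_table(path, sex: str | None = None):
    """Read screening tables back from :func:`export_table`'s layout.

    Re-validates all invariants; a violated invariant is rejected with the
    offending row/column named.  Returns a dict keyed by sex, or a single
    table when ``sex`` is given.
    """
    df = pd.read_csv(Path(path), sep=None, engine="python")
    pcols = [c for c in df.columns if c.startswith("h") and c[1:].isdigit()]
    percentiles = tuple(int(c[1:]) for c in pcols)
    out = {}
    for sx, part in df.groupby("sex", sort=False):
        heights = part[[f"h{p}" for p in percentiles]].to_numpy(float)
        weights = part[[f"w{p}" for p in percentiles]].to_numpy(float)
        out[sx] = ScreeningTable(sx, part["age_years"].to_numpy(float),
                                 percentiles, heights, weights)
    if sex is not None:
        return out[sex]
    return out
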