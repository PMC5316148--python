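"""LMS growth-reference machinery.

A growth reference parametrizes the distribution of a measurement (BMI,
height, ...) at each age and sex by three numbers: a Box-Cox power ``L``,
the median ``M``, and a coefficient of variation ``S``.  The z-score of a
measurement ``x`` is

    z = ((x/M)**L - 1) / (L*S)        for L != 0
    z = ln(x/M) / S                    for L == 0

and the inverse transform recovers the measurement at a given z-score,

    x = M * (1 + L*S*z)**(1/L)         for L != 0
    x = M * exp(S*z)                   for L == 0.

This module loads references from delimited text, interpolates the LMS
parameters between tabulated months, and exposes the forward, inverse and
percentile transforms that the classifiers and the screening-table builder
are built on.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError, OutOfRangeError, ReferenceFormatError
from .utils import INDICATORS, SEXES, validate_sex

logger = logging.getLogger(__name__)

#: Below this |L| the exact log-normal branch is used instead of the power
#: branch, which suffers catastrophic cancellation as L -> 0.
L_LOG_SWITCH = 1e-7

#: |z| beyond which a value is biologically implausible; logged, not rejected.
EXTREME_Z = 5.0


@dataclass(frozen=True)
class LmsRecord:
    """One (sex, age-in-months) row of LMS parameters for an indicator.

    ``M`` is in the indicator's units (kg/m^2 for BMI-for-age, cm for
    height-for-age); ``L`` and ``S`` are dimensionless.
    """

    sex: str
    age_months: int
    L: float
    M: float
    S: float

    def __post_init__(self) -> None:
        validate_sex(self.sex)
        if not self.M > 0:
            raise ValueError(f"M must be > 0, got {self.M}")
        if not self.S > 0:
            raise ValueError(f"S must be > 0, got {self.S}")


class GrowthReference:
    """A sex-partitioned LMS reference for one indicator.

    Records are sorted by age; duplicate (sex, age) rows are rejected.  A
    reference with gaps between tabulated months is allowed ("sparse") and
    queries between months are answered by component-wise linear
    interpolation of L, M and S.
    """

    def __init__(self, indicator: str, records: Iterable[LmsRecord]):
        if indicator not in INDICATORS:
            raise ValueError(f"indicator must be one of {INDICATORS}, got {indicator!r}")
        self.indicator = indicator
        by_sex: dict[str, list[LmsRecord]] = {s: [] for s in SEXES}
        for rec in records:
            by_sex[rec.sex].append(rec)
        for sex in SEXES:
            if not by_sex[sex]:
                raise ReferenceFormatError(f"reference has no {sex} records")
        self._tables: dict[str, dict[str, np.ndarray]] = {}
        self.sparse = False
        for sex, recs in by_sex.items():
            recs.sort(key=lambda r: r.age_months)
            ages = np.array([r.age_months for r in recs], dtype=float)
            dupes = ages[:-1][np.diff(ages) == 0]
            if dupes.size:
                raise ReferenceFormatError(
                    f"duplicate ({sex}, {int(dupes[0])}) row in {indicator} reference"
                )
            if np.any(np.diff(ages) > 1):
                self.sparse = True
            self._tables[sex] = {
                "ages": ages,
                "L": np.array([r.L for r in recs]),
                "M": np.array([r.M for r in recs]),
                "S": np.array([r.S for r in recs]),
            }

    def __len__(self) -> int:
        return sum(t["ages"].size for t in self._tables.values())

    @property
    def age_range(self) -> tuple[int, int]:
        """(min, max) months covered by *both* sexes."""
        lo = max(int(t["ages"][0]) for t in self._tables.values())
        hi = min(int(t["ages"][-1]) for t in self._tables.values())
        return lo, hi

    def ages(self, sex: str) -> np.ndarray:
        return self._tables[validate_sex(sex)]["ages"]

    def lms_at(self, sex: str, age_months: float) -> tuple[float, float, float]:
        """LMS parameters at an exact or interpolated age.

        Exactly tabulated months return the tabulated record unchanged;
        other ages return component-wise linear interpolation between the
        bracketing months.
        """
        t = self._tables[validate_sex(sex)]
        ages = t["ages"]
        if age_months < ages[0] or age_months > ages[-1]:
            raise OutOfRangeError(
                f"age {age_months} months outside {self.indicator} reference "
                f"coverage [{ages[0]:.0f}, {ages[-1]:.0f}] for {sex}"
            )
        L = float(np.interp(age_months, ages, t["L"]))
        M = float(np.interp(age_months, ages, t["M"]))
        S = float(np.interp(age_months, ages, t["S"]))
        return L, M, S


def lms_at_age(ref: GrowthReference, sex: str, age_months: float) -> tuple[float, float, float]:
    """Functional alias for :meth:`GrowthReference.lms_at`."""
    return ref.lms_at(sex, age_months)


# ---------------------------------------------------------------------------
# The LMS transforms


def zscore(x, L: float, M: float, S: float):
    """z-score of measurement ``x`` under LMS parameters.

    Accepts a scalar or array ``x``.  Strictly increasing in ``x``.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise DomainError("measurement must be > 0")
    if M <= 0 or S <= 0:
        raise DomainError("M and S must be > 0")
    if abs(L) < L_LOG_SWITCH:
        z = np.log(x / M) / S
    else:
        z = ((x / M) ** L - 1.0) / (L * S)
    if np.any(np.abs(z) > EXTREME_Z):
        logger.warning("|z| > %g encountered (max %.2f): biologically implausible value",
                       EXTREME_Z, float(np.max(np.abs(z))))
    return float(z) if z.ndim == 0 else z


def value_at_zscore(z, L: float, M: float, S: float):
    """Inverse LMS transform: the measurement sitting at z-score ``z``."""
    z = np.asarray(z, dtype=float)
    if M <= 0 or S <= 0:
        raise DomainError("M and S must be > 0")
    if abs(L) < L_LOG_SWITCH:
        x = M * np.exp(S * z)
    else:
        base = 1.0 + L * S * z
        if np.any(base <= 0):
            raise DomainError(
                f"z={np.asarray(z).ravel()} outside the transform's support "
                f"(1 + L*S*z must be > 0 with L={L}, S={S})"
            )
        x = M * base ** (1.0 / L)
    return float(x) if x.ndim == 0 else x


def value_at_percentile(p: float, L: float, M: float, S: float) -> float:
    """Measurement at the ``p``-th reference percentile, 0 < p < 100."""
    if not 0 < p < 100:
        raise DomainError(f"percentile must lie in (0, 100), got {p}")
    return value_at_zscore(stats.norm.ppf(p / 100.0), L, M, S)


# ---------------------------------------------------------------------------
# File loading

_CANONICAL_COLUMNS = ("sex", "age_months", "L", "M", "S")

_SEX_CODES = {
    "male": "male", "m": "male", "1": "male", "boy": "male", "boys": "male",
    "female": "female", "f": "female", "2": "female", "girl": "female", "girls": "female",
}


def _read_delimited(path) -> pd.DataFrame:
    # sep=None autodetects comma vs tab
    return pd.read_csv(path, sep=None, engine="python", dtype=str, comment="#",
                       skip_blank_lines=True)


def _load_records(path, column_map=None, sex=None) -> list[LmsRecord]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = _read_delimited(path)
    if column_map:
        df = df.rename(columns=dict(column_map))
    df.columns = [c.strip() for c in df.columns]
    needed = set(_CANONICAL_COLUMNS) - ({"sex"} if sex else set())
    missing = needed - set(df.columns)
    if missing:
        raise ReferenceFormatError(
            f"{path}: missing column(s) {sorted(missing)}; found {list(df.columns)}"
        )
    records: list[LmsRecord] = []
    problems: list[str] = []
    seen: set[tuple[str, int]] = set()
    for i, row in df.iterrows():
        lineno = i + 2  # 1-based, after the header line
        try:
            sx = _SEX_CODES.get(str(sex if sex else row["sex"]).strip().lower())
            if sx is None:
                raise ValueError(f"unrecognized sex {row.get('sex')!r}")
            age = int(float(row["age_months"]))
            L, M, S = (float(row[c]) for c in ("L", "M", "S"))
            if (sx, age) in seen:
                raise ValueError(f"duplicate ({sx}, {age}) row")
            seen.add((sx, age))
            records.append(LmsRecord(sx, age, L, M, S))
        except (ValueError, TypeError) as exc:
            problems.append(f"{path}:{lineno}: {exc}")
    if problems:
        raise ReferenceFormatError("\n".join(problems))
    return records


def load_reference(
    path,
    indicator: str,
    column_map: Mapping[str, str] | None = None,
) -> GrowthReference:
    """Load an LMS reference from delimited text (comma or tab).

    The expected header is ``sex,age_months,L,M,S``; ``column_map`` renames
    file columns onto that dialect (e.g. ``{"Month": "age_months"}`` for
    WHO-published layouts).  Malformed rows are reported with their line
    numbers; duplicate (sex, age) rows and non-positive M or S are rejected.
    """
    return GrowthReference(indicator, _load_records(path, column_map=column_map))


def load_reference_pair(male_path, female_path, indicator: str,
                        column_map: Mapping[str, str] | None = None) -> GrowthReference:
    """Load a reference published as one file per sex (the WHO 2007 layout).

    The WHO "expanded tables" carry columns ``Month,L,M,S`` and no sex
    column; the default ``column_map`` accepts that layout unedited.
    """
    if column_map is None:
        column_map = {"Month": "age_months", "month": "age_months", "Age": "age_months"}
    recs = _load_records(male_path, column_map=column_map, sex="male")
    recs += _load_records(female_path, column_map=column_map, sex="female")
    return GrowthReference(indicator, recs)
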