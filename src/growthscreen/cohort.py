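"""Synthetic study cohorts and descriptive summaries.

The generator emulates the statistical structure of a school-age clinic
sample: ages uniform on an eligibility window of completed months, sex a
Bernoulli draw, and a bivariate-normal pair of (height, BMI) z-scores
that is pushed through the LMS references to obtain height and BMI on the
measurement scale.  Weight is derived as ``BMI * (height/100)^2`` rather
than simulated directly, which guarantees the BMI-z marginal and keeps
weight and height coherent within each child.

Defaults reproduce the validation-study conditions: n = 168, ages 72-143
completed months, 47.6% girls, BMI z ~ N(0.4, 1.0^2).  The height-z
marginal N(0.3, 1.0^2) and the z-correlation 0.3 are package choices (the
study reports no joint structure) picked so the synthetic height and
weight marginals land near the study's descriptives.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .bmi import ChildRecord, bmi_zscore, compute_bmi
from .errors import CoverageError
from .lms import GrowthReference, value_at_zscore
from .utils import round_half_up


@dataclass(frozen=True)
class CohortSpec:
    """Distributional parameters for a synthetic cohort."""

    n: int = 168
    seed: int = 0
    age_range_months: tuple[int, int] = (72, 143)
    female_fraction: float = 0.476
    bmi_z_mean: float = 0.4
    bmi_z_sd: float = 1.0
    height_z_mean: float = 0.3
    height_z_sd: float = 1.0
    z_correlation: float = 0.3
    round_weight: bool = True
    round_height: bool = True

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not 0 <= self.female_fraction <= 1:
            raise ValueError("female_fraction must lie in [0, 1]")
        if self.bmi_z_sd < 0 or self.height_z_sd < 0:
            raise ValueError("z-score standard deviations must be >= 0")
        if not -1 <= self.z_correlation <= 1:
            raise ValueError("|z_correlation| must be <= 1")
        if self.age_range_months[0] > self.age_range_months[1]:
            raise ValueError("age range must be non-decreasing")


def generate_cohort(
    spec: CohortSpec,
    height_ref: GrowthReference,
    bmi_ref: GrowthReference,
) -> list[ChildRecord]:
    """Draw a reproducible synthetic cohort of :class:`ChildRecord`.

    The same spec (including its seed) always yields the identical cohort.
    """
    lo, hi = spec.age_range_months
    for ref in (height_ref, bmi_ref):
        rlo, rhi = ref.age_range
        if lo < rlo or hi > rhi:
            raise CoverageError(
                f"{ref.indicator} reference covers [{rlo}, {rhi}] months but the "
                f"cohort needs [{lo}, {hi}]"
            )
    rng = np.random.default_rng(spec.seed)
    ages = rng.integers(lo, hi + 1, size=spec.n)
    female = rng.random(spec.n) < spec.female_fraction
    # Bivariate normal via explicit Cholesky factors; exact for sd = 0.
    u1 = rng.standard_normal(spec.n)
    u2 = rng.standard_normal(spec.n)
    rho = spec.z_correlation
    height_z = spec.height_z_mean + spec.height_z_sd * u1
    bmi_z = spec.bmi_z_mean + spec.bmi_z_sd * (rho * u1 + np.sqrt(1 - rho**2) * u2)
    children = []
    for i in range(spec.n):
        sex = "female" if female[i] else "male"
        age = int(ages[i])
        height = value_at_zscore(height_z[i], *height_ref.lms_at(sex, age))
        bmi = value_at_zscore(bmi_z[i], *bmi_ref.lms_at(sex, age))
        weight = bmi * (height / 100.0) ** 2
        if spec.round_height:
            height = round_half_up(height, 1)
        if spec.round_weight:
            weight = round_half_up(weight, 1)
        children.append(ChildRecord(f"S{i:04d}", sex, age, weight, height))
    return children


# ---------------------------------------------------------------------------
# Descriptive summaries

#: Age bands of the study's descriptive table, in completed months.
DEFAULT_AGE_BANDS = (("6-8 y", 72, 107), ("9-11 y", 108, 143))


@dataclass(frozen=True)
class CohortSummary:
    """Mean +/- SD per (sex x age band) stratum plus totals, with gender t-tests.

    ``table`` has one row per stratum and per variable columns ``<var>_mean``
    / ``<var>_sd``; ``p_values`` maps each age band to the Welch t-test
    p-value for the male-female comparison of each variable.  Strata with a
    single member carry NaN SDs and are listed in ``degenerate_strata``.
    """

    table: pd.DataFrame
    p_values: dict[str, dict[str, float]]
    degenerate_strata: tuple

    @property
    def n(self) -> int:
        return int(self.table.loc[self.table["stratum"] == "total", "n"].iloc[0])


_SUMMARY_VARS = ("age_months", "weight_kg", "height_cm", "bmi", "bmi_z")


def summarize_cohort(
    cohort: Sequence[ChildRecord],
    bmi_ref: GrowthReference,
    age_bands=DEFAULT_AGE_BANDS,
) -> CohortSummary:
    """Descriptive summary in the study's layout: sex x age band strata.

    Reports mean and SD of age, weight, height, BMI and BMI z-score per
    stratum and in total, and a Welch (unequal-variance) two-sample t-test
    per age band for the difference between boys and girls.
    """
    if not cohort:
        raise ValueError("cohort is empty")
    df = pd.DataFrame(
        {
            "sex": [c.sex for c in cohort],
            "age_months": [c.age_months for c in cohort],
            "weight_kg": [c.weight_kg for c in cohort],
            "height_cm": [c.height_cm for c in cohort],
            "bmi": [compute_bmi(c.weight_kg, c.height_cm) for c in cohort],
            "bmi_z": [bmi_zscore(c, bmi_ref) for c in cohort],
        }
    )
    rows = []
    degenerate = []
    p_values: dict[str, dict[str, float]] = {}

    def _row(name, sub):
        entry = {"stratum": name, "n": len(sub)}
        for v in _SUMMARY_VARS:
            entry[f"{v}_mean"] = sub[v].mean()
            entry[f"{v}_sd"] = sub[v].std(ddof=1)
        if len(sub) < 2:
            degenerate.append(name)
        return entry

    for band, lo, hi in age_bands:
        in_band = df[(df.age_months >= lo) & (df.age_months <= hi)]
        boys = in_band[in_band.sex == "male"]
        girls = in_band[in_band.sex == "female"]
        rows.append(_row(f"male {band}", boys))
        rows.append(_row(f"female {band}", girls))
        p_values[band] = {}
        for v in _SUMMARY_VARS:
            if len(boys) >= 2 and len(girls) >= 2:
                p = stats.ttest_ind(boys[v], girls[v], equal_var=False).pvalue
            else:
                p = float("nan")
            p_values[band][v] = float(p)
    rows.append(_row("total", df))
    table = pd.DataFrame(rows)
    if int(table.loc[table.stratum != "total", "n"].sum()) != len(df):
        # children outside all bands would silently vanish from strata
        raise ValueError("age bands do not partition the cohort")
    return CohortSummary(table=table, p_values=p_values,
                         degenerate_strata=tuple(degenerate))


# ---------------------------------------------------------------------------
# Cohort file I/O (shared dialect: child_id,sex,age_months,weight_kg,height_cm)

COHORT_COLUMNS = ("child_id", "sex", "age_months", "weight_kg", "height_cm")


def write_cohort(cohort: Sequence[ChildRecord], path) -> None:
    pd.DataFrame(
        [(c.child_id, c.sex, c.age_months, c.weight_kg, c.height_cm) for c in cohort],
        columns=COHORT_COLUMNS,
    ).to_csv(path, index=False, float_format="%.1f")


def read_cohort(path) -> list[ChildRecord]:
    df = pd.read_csv(path, sep=None, engine="python")
    missing = set(COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing cohort column(s) {sorted(missing)}")
    return [
        ChildRecord(str(r.child_id), str(r.sex), int(r.age_months),
                    float(r.weight_kg), float(r.height_cm))
        for r in df.itertuples()
    ]
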