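"""Synthetic LMS reference curves for testing and simulation.

These are NOT the published WHO 2007 tables.  They are smooth synthetic
curves whose medians, coefficients of variation and Box-Cox powers sit in
the broadly realistic range for school-age children (heights rising from
~110 cm at 5 y to ~175 cm at 19 y; median BMI rising from ~15 to ~22
kg/m^2 with right skew, L < 0), so that every pipeline property — grid
monotonicity, classifier agreement structure, z-score round trips — can
be exercised without external data.  Anything that depends on the real
WHO 2007 numbers (e.g. the 19.16 kg/m^2 cutoff for boys at 122 months)
requires the real tables to be supplied by the user.

Curves are piecewise-linear through age anchors, which keeps every
parameter, and hence the +1 SD cutoffs and percentile heights, strictly
increasing in age — the regime in which the screening instrument's
min-of-bracketing-cells rule dominates the direct BMI cutoff.
"""

from __future__ import annotations

import numpy as np

from .lms import GrowthReference, LmsRecord

# Age anchors in months and per-sex parameter anchors (piecewise linear).
_ANCHORS = {
    "height_for_age": {
        "ages": [60, 120, 180, 228],
        "male": {"L": [1.0, 1.0, 1.0, 1.0],
                 "M": [110.0, 137.8, 163.2, 176.5],
                 "S": [0.038, 0.041, 0.043, 0.044]},
        "female": {"L": [1.0, 1.0, 1.0, 1.0],
                   "M": [109.4, 138.6, 161.7, 163.4],
                   "S": [0.039, 0.042, 0.041, 0.040]},
    },
    "bmi_for_age": {
        "ages": [60, 120, 180, 228],
        "male": {"L": [-0.9, -1.3, -1.7, -1.9],
                 "M": [15.3, 16.4, 19.2, 21.9],
                 "S": [0.085, 0.120, 0.135, 0.130]},
        "female": {"L": [-0.9, -1.4, -1.8, -2.0],
                   "M": [15.2, 16.6, 19.9, 21.4],
                   "S": [0.090, 0.125, 0.130, 0.125]},
    },
}


def make_synthetic_reference(
    indicator: str,
    age_range: tuple[int, int] = (60, 228),
) -> GrowthReference:
    """Build a synthetic month-by-month LMS reference for one indicator."""
    spec = _ANCHORS[indicator]
    lo, hi = age_range
    months = np.arange(lo, hi + 1)
    records = []
    for sex in ("male", "female"):
        pars = spec[sex]
        L = np.interp(months, spec["ages"], pars["L"])
        M = np.interp(months, spec["ages"], pars["M"])
        S = np.interp(months, spec["ages"], pars["S"])
        records += [LmsRecord(sex, int(m), float(l), float(mu), float(s))
                    for m, l, mu, s in zip(months, L, M, S)]
    return GrowthReference(indicator, records)


def synthetic_reference_pair(age_range: tuple[int, int] = (60, 228)):
    """(bmi_for_age, height_for_age) synthetic references, month-by-month."""
    return (make_synthetic_reference("bmi_for_age", age_range),
            make_synthetic_reference("height_for_age", age_range))
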