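"""End-to-end comparison of the two screening arms.

Runs every child through both classifiers, collects the per-child audit
trail, cross-classifies into a 2x2 table and computes percent agreement.
Children the references or tables cannot cover are excluded with a
recorded reason, never silently dropped: classified + excluded = input.
Machine-readable outputs are written atomically and are byte-identical
across re-runs with identical inputs.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from . import __version__
from .agreement import AgreementReport, TwoByTwoTable, crosstab, format_report, percent_agreement
from .bmi import ChildRecord, classify_who
from .errors import GrowthScreenError, OutOfRangeError
from .lms import GrowthReference
from .screening import ScreeningTable, classify_simplified

logger = logging.getLogger(__name__)


@dataclass
class ComparisonResult:
    """Everything one comparison run produced."""

    classified: pd.DataFrame
    exclusions: pd.DataFrame
    table: TwoByTwoTable
    report: AgreementReport


def run_comparison(
    cohort: Sequence[ChildRecord],
    bmi_ref: GrowthReference,
    tables: Mapping[str, ScreeningTable],
) -> ComparisonResult:
    """Classify a cohort with both arms and quantify their agreement.

    ``tables`` maps sex -> screening table.  Raises on an empty cohort;
    out-of-coverage children land in ``exclusions`` with a reason.
    """
    if not cohort:
        raise GrowthScreenError("cohort is empty; nothing to classify")
    rows, excluded, pairs = [], [], []
    for child in cohort:
        try:
            who = classify_who(child, bmi_ref)
            simple = classify_simplified(child, tables[child.sex])
        except (OutOfRangeError, KeyError) as exc:
            excluded.append({
                "child_id": child.child_id,
                "sex": child.sex,
                "age_months": child.age_months,
                "reason": f"{type(exc).__name__}: {exc}",
            })
            continue
        pairs.append((simple.label, who.label))
        rows.append({
            "child_id": child.child_id,
            "sex": child.sex,
            "age_months": child.age_months,
            "weight_kg": child.weight_kg,
            "height_cm": child.height_cm,
            "bmi": round(who.detail["bmi"], 4),
            "bmi_z": round(who.detail["bmi_z"], 4),
            "who_threshold": round(who.detail["threshold"], 4),
            "who_status": who.label,
            "grid_weights": "|".join(f"{w:.1f}" for w in simple.detail["grid_weights"]),
            "grid_threshold": simple.detail["threshold"],
            "grid_clamped": simple.detail["clamped"],
            "simplified_status": simple.label,
        })
    if not rows:
        raise GrowthScreenError("every child was excluded; no classifications to compare")
    table = crosstab(pairs)
    result = ComparisonResult(
        classified=pd.DataFrame(rows),
        exclusions=pd.DataFrame(excluded, columns=["child_id", "sex", "age_months", "reason"]),
        table=table,
        report=percent_agreement(table),
    )
    logger.info("classified %d children (%d excluded); 2x2 = (%d, %d, %d, %d)",
                len(rows), len(excluded), table.a, table.b, table.c, table.d)
    return result


def _atomic_write(path: Path, text: str) -> None:
    tmp = path.with_suffix(path.suffix + ".tmp")
    tmp.write_text(text)
    os.replace(tmp, path)


def write_outputs(result: ComparisonResult, out_dir, seed: Optional[int] = None) -> dict:
    """Persist a run: classified cohort, exclusions, 2x2 table and report.

    Returns the paths written.  JSON carries full-precision statistics;
    the text report carries the printed (rounded/truncated) form.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "classified": out / "classified.csv",
        "exclusions": out / "exclusions.csv",
        "agreement": out / "agreement.json",
        "report": out / "report.txt",
    }
    _atomic_write(paths["classified"], result.classified.to_csv(index=False))
    _atomic_write(paths["exclusions"], result.exclusions.to_csv(index=False))
    rep = result.report
    payload = {
        "version": __version__,
        "seed": seed,
        "n_classified": int(len(result.classified)),
        "n_excluded": int(len(result.exclusions)),
        "counts": {k: getattr(result.table, k) for k in "abcd"},
        "overall_pct": rep.overall_pct,
        "positive_pct": rep.positive_pct,
        "negative_pct": rep.negative_pct,
        "cell_pct": rep.cell_pct,
        "presentation": rep.presentation(),
    }
    _atomic_write(paths["agreement"], json.dumps(payload, indent=2, sort_keys=True) + "\n")
    _atomic_write(paths["report"], format_report(rep) + "\n")
    return paths
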