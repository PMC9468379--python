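"""End-to-end cohort evaluation: contour metrics -> DVH flags -> cohort
table -> pass/fail statistics.

This is the library form of the ``contourqa cohort`` command: it takes
paired AI/edited structure sets (typically synthetic studies from
:mod:`contourqa.phantoms`, or masks loaded via :mod:`contourqa.rt_io`)
and produces the per-(patient, structure) cohort table consumed by
:mod:`contourqa.stats`.
"""

from __future__ import annotations

import logging

import pandas as pd

from .config import RunConfig
from .dvh import DoseGrid, compute_dvh, flag_dvh
from .errors import ContourQAError, GroupingError
from .grid import StructureMask
from .metrics import compare_structures
from .stats import COHORT_COLUMNS, GroupComparison, compare_pass_fail

__all__ = ["evaluate_pair", "evaluate_study", "run_cohort"]

log = logging.getLogger("contourqa")


def evaluate_pair(
    ai: StructureMask,
    edited: StructureMask,
    dose: DoseGrid | None,
    config: RunConfig,
) -> dict:
    """One cohort-table row for one AI/edited structure pair."""
    report = compare_structures(
        ai,
        edited,
        delta=config.delta_mm,
        hd_p=config.hd_percentile,
        eff_direction=config.eff_direction,
    )
    row = {
        "structure": ai.name,
        "dice": report.dice,
        "hd95": report.hd95,
        "eff": report.eff,
        "dvh_pass": True,
        "zero_dose": True,
    }
    if dose is not None and not report.degenerate:
        curve_ai = compute_dvh(ai, dose, config.longitudinal_factor, config.dvh_bin_cgy)
        curve_ed = compute_dvh(
            edited, dose, config.longitudinal_factor, config.dvh_bin_cgy
        )
        result = flag_dvh(
            curve_ai,
            curve_ed,
            vol_tol=config.vol_tolerance,
            dose_window=config.dose_window_cgy,
            min_dose=config.min_dose_cgy,
        )
        row["dvh_pass"] = result.passed
        row["zero_dose"] = curve_ai.is_zero_dose and curve_ed.is_zero_dose
        row["dvh_max_discrepancy"] = result.max_discrepancy
    return row


def evaluate_study(study, config: RunConfig) -> list[dict]:
    """Cohort-table rows for one study (an object with ``patient_id``,
    ``ai``/``edited`` mask dicts and optional ``dose``)."""
    rows = []
    for name, ai_mask in study.ai.items():
        edited_mask = study.edited[name]
        try:
            row = evaluate_pair(ai_mask, edited_mask, study.dose, config)
        except ContourQAError as exc:
            log.warning("%s/%s: %s", study.patient_id, name, exc)
            continue
        row["patient"] = study.patient_id
        rows.append(row)
    return rows


def run_cohort(
    studies, config: RunConfig | None = None
) -> tuple[pd.DataFrame, list[GroupComparison] | None]:
    """Evaluate a list of studies into a cohort table plus, when both DVH
    outcome groups are populated, the pass/fail KS comparisons.

    A cohort in which every structure passes (or every structure fails)
    has no contrast to test; the grouping error is logged and ``None`` is
    returned for the comparisons, with the table intact.
    """
    config = config or RunConfig()
    rows = []
    for study in studies:
        rows.extend(evaluate_study(study, config))
    table = pd.DataFrame(rows)
    if not table.empty:
        lead = [c for c in COHORT_COLUMNS if c in table.columns]
        table = table[lead + [c for c in table.columns if c not in lead]]
    comparisons = None
    try:
        comparisons = compare_pass_fail(table)
    except GroupingError as exc:
        log.warning("pass/fail comparison skipped: %s", exc)
    return table, comparisons
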