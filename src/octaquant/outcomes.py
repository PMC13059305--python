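"""Outcome definitions: ETDRS step scale, DR progression, VA decline.

Diabetic-retinopathy severity graded on the ETDRS photographic scale is
collapsed to a 5-step scale (level 10 -> step 1, levels 15/20 -> step 2,
level 35 -> step 3, level 43 -> step 4, level 47 -> step 5).  Progression is
an increase of >= 2 steps between baseline and follow-up.  Visual-acuity
decline is a worsening of more than one chart line, with one line taken as
0.1 logMAR (strict inequality).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: ETDRS level -> collapsed step
ETDRS_STEP = {10: 1, 15: 2, 20: 2, 35: 3, 43: 4, 47: 5}

#: representative ETDRS level per step (used by the cohort simulator)
STEP_LEVEL = {1: 10, 2: 20, 3: 35, 4: 43, 5: 47}

LOGMAR_PER_LINE = 0.1
_TIE_TOL = 1e-9

OUTCOME_COLUMNS = ("step_change", "dr_progressed", "va_declined")


def etdrs_step(level: int) -> int:
    """Collapsed step for an ETDRS severity level; errors on unmapped levels."""
    try:
        return ETDRS_STEP[int(level)]
    except (KeyError, ValueError, TypeError):
        raise ValueError(
            f"ETDRS level {level!r} is outside the mapped set {sorted(ETDRS_STEP)}"
        ) from None


def dr_progression(etdrs_baseline: int, etdrs_followup: int) -> tuple[bool, int]:
    """(progressed, step change) for a pair of visits; progressed iff >= +2 steps."""
    change = etdrs_step(etdrs_followup) - etdrs_step(etdrs_baseline)
    return change >= 2, change


def va_decline(va_baseline_logmar: float, va_followup_logmar: float) -> bool:
    """True when acuity worsened by strictly more than one line (0.1 logMAR)."""
    if not (np.isfinite(va_baseline_logmar) and np.isfinite(va_followup_logmar)):
        raise ValueError("logMAR values must be finite")
    return (va_followup_logmar - va_baseline_logmar) > LOGMAR_PER_LINE + _TIE_TOL


def label_cohort(table: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Append outcome labels to an eye-level table and tabulate the groups.

    Rows with missing baseline/follow-up ETDRS or VA fields are dropped with
    a logged count.  Returns the labelled table (columns ``step_change``,
    ``dr_progressed``, ``va_declined`` appended) and a summary dict with
    per-group counts and percentages.
    """
    required = ["etdrs_baseline", "etdrs_followup", "va_baseline", "va_followup"]
    missing_cols = [c for c in required if c not in table.columns]
    if missing_cols:
        raise ValueError(f"cohort table lacks outcome columns: {missing_cols}")
    out = table.copy()
    complete = out[required].notna().all(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.info("label_cohort: dropped %d rows with incomplete outcome fields", n_dropped)
    out = out.loc[complete].copy()

    if len(out):
        steps_b = out["etdrs_baseline"].map(etdrs_step)
        steps_f = out["etdrs_followup"].map(etdrs_step)
        out["step_change"] = (steps_f - steps_b).astype(int)
        out["dr_progressed"] = out["step_change"] >= 2
        out["va_declined"] = (
            out["va_followup"] - out["va_baseline"] > LOGMAR_PER_LINE + _TIE_TOL
        )
    else:
        for col in OUTCOME_COLUMNS:
            out[col] = pd.Series(dtype=bool if col != "step_change" else int)

    n = len(out)
    n_prog = int(out["dr_progressed"].sum()) if n else 0
    n_decl = int(out["va_declined"].sum()) if n else 0
    summary = {
        "n_eyes": n,
        "n_dropped_incomplete": n_dropped,
        "n_progressed": n_prog,
        "pct_progressed": 100.0 * n_prog / n if n else 0.0,
        "n_va_declined": n_decl,
        "pct_va_declined": 100.0 * n_decl / n if n else 0.0,
    }
    return out, summary
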