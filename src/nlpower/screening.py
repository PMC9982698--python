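"""Planning classifier-screened human abstraction.

Under screened abstraction, only passages scoring at or above a screening
threshold are reviewed by humans; the human review is treated as the gold
standard, so no false-positive patient survives review and the strategy's
specificity is exactly 1.  Its patient-level sensitivity, however, can fall
below that of the classifier alone: a truly-positive patient whose only
true passages score *below* the threshold is missed even if some of their
false-positive passages score above it (the reviewer rejects those).

Workload follows a stopping rule: per patient, flagged passages are reviewed
in chronological order until the first human-confirmed positive (after which
the patient's outcome is known), or exhaustively within the observation
window if none is confirmed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .design import ClassifierPerformance, SolveStatus, TrialDesign
from .power import solve_detectable_rd

__all__ = [
    "ScreeningPlan",
    "EffortEstimate",
    "screened_patient_sensitivity",
    "screening_workload",
    "screening_tradeoff",
    "plans_to_frame",
    "effort_estimate",
]


@dataclass(frozen=True)
class ScreeningPlan:
    """One row of the sensitivity-versus-workload trade-off."""

    threshold: float
    patient_sensitivity: float
    n_passages_flagged: int
    n_passages_reviewed: int
    detectable_rd: float  # NaN when status is not "ok"
    status: str
    window_days: int


@dataclass(frozen=True)
class EffortEstimate:
    """Linear scaling of review units to abstractor-hours and cost."""

    n_units: int
    rate: float  # units per abstractor-hour
    hours: float
    cost: float | None = None


def _check_window(passages: pd.DataFrame, window_days: int) -> None:
    off = passages["day_offset"]
    bad = passages[(off < 0) | (off > window_days)]
    if len(bad):
        raise ValueError(
            f"{len(bad)} passage(s) with day_offset outside [0, {window_days}]; "
            f"first offending passage_id: {bad.iloc[0]['passage_id']!r}"
        )


def screened_patient_sensitivity(passages: pd.DataFrame, threshold: float) -> float:
    """Patient-level sensitivity of threshold screening plus human review.

    The fraction of truly-positive patients (any gold-positive passage) who
    have at least one gold-positive passage scoring at or above the
    threshold.  False-positive passages above threshold do not detect a
    patient: the reviewer rejects them.
    """
    pos = passages[passages["gold_label"] == 1]
    true_patients = pos["patient_id"].unique()
    if len(true_patients) == 0:
        raise ValueError("no truly-positive patients: sensitivity is undefined")
    detected = pos[pos["score"] >= threshold]["patient_id"].nunique()
    return detected / len(true_patients)


def screening_workload(
    passages: pd.DataFrame, threshold: float, window_days: int = 30
) -> tuple[int, int]:
    """Flagged and reviewed passage counts at a screening threshold.

    ``n_flagged`` counts all passages with score >= threshold inside the
    window.  ``n_reviewed`` applies the stopping rule per patient: flagged
    passages in chronological order (day_offset, then note_id, then
    passage_id as deterministic tie-breaks) up to and including the first
    gold-positive one, or all of them if none is positive.
    """
    _check_window(passages, window_days)
    flagged = passages[passages["score"] >= threshold]
    n_flagged = len(flagged)
    if n_flagged == 0:
        return 0, 0
    ordered = flagged.sort_values(
        ["patient_id", "day_offset", "note_id", "passage_id"], kind="stable"
    )
    n_reviewed = 0
    for _pid, grp in ordered.groupby("patient_id", sort=False):
        labels = grp["gold_label"].to_numpy()
        hits = labels.nonzero()[0]
        n_reviewed += int(hits[0]) + 1 if len(hits) else len(labels)
    return n_flagged, n_reviewed


def screening_tradeoff(
    passages: pd.DataFrame,
    thresholds: Sequence[float],
    design: TrialDesign,
    window_days: int = 30,
) -> list[ScreeningPlan]:
    """Per-threshold screened sensitivity, workload, and detectable RD.

    The detectable risk difference treats screened abstraction as a
    classifier with the screened patient-level sensitivity and specificity
    exactly 1.  A threshold whose screened sensitivity is 0 leaves the
    classifier non-identifiable; the row carries a status, not a number.
    """
    plans = []
    for t in sorted(thresholds):
        if not 0.0 <= t <= 1.0:
            raise ValueError(f"threshold must lie in [0, 1], got {t}")
        sens = screened_patient_sensitivity(passages, t)
        n_flagged, n_reviewed = screening_workload(passages, t, window_days)
        sol = solve_detectable_rd(design, ClassifierPerformance(sens, 1.0))
        plans.append(
            ScreeningPlan(
                threshold=t,
                patient_sensitivity=sens,
                n_passages_flagged=n_flagged,
                n_passages_reviewed=n_reviewed,
                detectable_rd=sol.rd if sol.defined else float("nan"),
                status=sol.status.value,
                window_days=window_days,
            )
        )
    return plans


def plans_to_frame(plans: Sequence[ScreeningPlan]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "threshold": [p.threshold for p in plans],
            "patient_sensitivity": [p.patient_sensitivity for p in plans],
            "n_flagged": [p.n_passages_flagged for p in plans],
            "n_reviewed": [p.n_passages_reviewed for p in plans],
            "detectable_rd": [p.detectable_rd for p in plans],
            "status": [p.status for p in plans],
        }
    )


def effort_estimate(
    n_units: int,
    *,
    units_per_hour: float | None = None,
    hours_per_unit: float | None = None,
    hourly_cost: float | None = None,
) -> EffortEstimate:
    """Linear abstraction-effort scaling, optionally costed.

    Exactly one of ``units_per_hour`` or ``hours_per_unit`` must be given
    and positive.
    """
    if n_units < 0:
        raise ValueError(f"n_units must be >= 0, got {n_units}")
    if (units_per_hour is None) == (hours_per_unit is None):
        raise ValueError("give exactly one of units_per_hour or hours_per_unit")
    if units_per_hour is not None:
        if units_per_hour <= 0:
            raise ValueError(f"units_per_hour must be positive, got {units_per_hour}")
        rate = units_per_hour
        hours = n_units / units_per_hour
    else:
        if hours_per_unit <= 0:
            raise ValueError(f"hours_per_unit must be positive, got {hours_per_unit}")
        rate = 1.0 / hours_per_unit
        hours = n_units * hours_per_unit
    cost = hours * hourly_cost if hourly_cost is not None else None
    return EffortEstimate(n_units=n_units, rate=rate, hours=hours, cost=cost)
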