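"""Hierarchical classifier evaluation: passages -> notes -> patients.

A text classifier scores *passages*; study outcomes live at the *note* and
*patient* level.  Scores aggregate upward by maximum (a unit is as positive
as its most positive passage) and gold labels by union (a note/patient is
positive if any constituent passage is).  Evaluation then follows the usual
binary-classification machinery — ROC, precision-recall, confusion-matrix
metrics at a threshold — except that every count is optionally weighted, so
that a validation sample which oversampled a stratum (e.g. ADRD patients at
50% when the trial runs at 11%) can be reweighted to the target population.

The decision rule throughout is ``score >= threshold  =>  positive``.
"""

from __future__ import annotations

from dataclasses import dataclass
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "aggregate",
    "stratum_weights",
    "roc_curve",
    "pr_curve",
    "metrics_at_threshold",
    "threshold_for_sensitivity",
    "stratum_weighted_prevalence",
    "ThresholdMetrics",
    "ThresholdSelection",
    "CurveResult",
]

PASSAGE_COLUMNS = (
    "patient_id",
    "note_id",
    "passage_id",
    "day_offset",
    "score",
    "gold_label",
    "stratum",
)


def aggregate(
    passages: pd.DataFrame,
    level: str,
    roster: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Aggregate passage scores and labels to note or patient level.

    Parameters
    ----------
    passages : DataFrame
        Needs ``patient_id``, ``score``, ``gold_label``, ``stratum`` (and
        ``note_id`` when ``level="note"``).
    level : {"note", "patient"}
    roster : DataFrame, optional
        Patient-level frame with ``patient_id`` and ``stratum``.  Patients in
        the roster with no passages enter as score-0, label-0 units — a
        patient with no notes in the window genuinely had no documented
        outcome.

    Returns
    -------
    DataFrame with columns unit_id, patient_id, level, score (max over
    constituents), gold_label (union), stratum, weight (1.0).

    Raises
    ------
    ValueError if a patient carries more than one stratum.
    """
    if level not in ("note", "patient"):
        raise ValueError(f"level must be 'note' or 'patient', got {level!r}")
    if len(passages) == 0 and roster is None:
        raise ValueError("cannot aggregate an empty passage collection")

    by_patient = passages.groupby("patient_id")["stratum"].nunique()
    conflicted = by_patient[by_patient > 1]
    if len(conflicted):
        raise ValueError(
            "conflicting stratum within patient(s): "
            + ", ".join(map(str, conflicted.index.tolist()))
        )

    keys = ["patient_id"] if level == "patient" else ["patient_id", "note_id"]
    agg = (
        passages.groupby(keys, sort=True)
        .agg(score=("score", "max"), gold_label=("gold_label", "max"), stratum=("stratum", "first"))
        .reset_index()
    )
    if level == "patient":
        agg["unit_id"] = agg["patient_id"].astype(str)
    else:
        agg["unit_id"] = agg["patient_id"].astype(str) + "|" + agg["note_id"].astype(str)

    if roster is not None and level == "patient":
        missing = roster[~roster["patient_id"].isin(agg["patient_id"])]
        if len(missing):
            extra = pd.DataFrame(
                {
                    "patient_id": missing["patient_id"].values,
                    "score": 0.0,
                    "gold_label": 0,
                    "stratum": missing["stratum"].values,
                    "unit_id": missing["patient_id"].astype(str).values,
                }
            )
            agg = pd.concat([agg, extra], ignore_index=True)

    agg["level"] = level
    agg["weight"] = 1.0
    cols = ["unit_id", "patient_id", "level", "score", "gold_label", "stratum", "weight"]
    if level == "note":
        cols.insert(2, "note_id")
    return agg[cols].sort_values("unit_id", kind="stable").reset_index(drop=True)


def stratum_weights(
    units: pd.DataFrame, target_weights: Mapping[str, float]
) -> np.ndarray:
    """Per-unit weights that reweight strata to target population shares.

    A unit in stratum *s* receives ``target_share_s / observed_share_s``, so
    weighted stratum totals match the target mixture while the total weight
    stays at the number of units.  This is the deterministic counterpart of
    resampling the validation set to trial prevalence.
    """
    total = float(sum(target_weights.values()))
    if not math.isclose(total, 1.0, abs_tol=1e-9):
        raise ValueError(f"target weights must sum to 1, got {total}")
    counts = units["stratum"].value_counts()
    unknown = set(counts.index) - set(target_weights)
    if unknown:
        raise ValueError(f"no target weight for strata: {sorted(map(str, unknown))}")
    n = len(units)
    w = np.empty(n, dtype=float)
    strat = units["stratum"].to_numpy()
    for s, share in target_weights.items():
        mask = strat == s
        if mask.any():
            w[mask] = share / (mask.sum() / n)
    return w


def _scores_labels_weights(units: pd.DataFrame, weights) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    y = units["gold_label"].to_numpy(dtype=int)
    s = units["score"].to_numpy(dtype=float)
    if weights is None:
        w = units["weight"].to_numpy(dtype=float) if "weight" in units else np.ones(len(units))
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != s.shape:
            raise ValueError("weights length must match units")
    return s, y, w


@dataclass(frozen=True)
class CurveResult:
    """An ROC or precision-recall curve with its area."""

    points: np.ndarray  # (k, 2) of (x, y): (FPR, TPR) or (recall, precision)
    thresholds: np.ndarray
    area: float
    kind: str  # "roc" | "pr"
    level: str | None = None

    def to_frame(self) -> pd.DataFrame:
        x, y = ("fpr", "tpr") if self.kind == "roc" else ("recall", "precision")
        k = len(self.thresholds)
        # ROC curves carry a prepended (0, 0) anchor without a threshold.
        pad = len(self.points) - k
        thr = np.concatenate([np.full(pad, np.nan), self.thresholds])
        return pd.DataFrame({x: self.points[:, 0], y: self.points[:, 1], "threshold": thr})


def _sweep(units: pd.DataFrame, weights) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, float]:
    """Cumulative weighted TP/FP over descending distinct thresholds."""
    s, y, w = _scores_labels_weights(units, weights)
    order = np.argsort(-s, kind="stable")
    s, y, w = s[order], y[order], w[order]
    ctp = np.cumsum(w * y)
    cfp = np.cumsum(w * (1 - y))
    # keep the last index of each tie block (rule is score >= threshold)
    last = np.r_[s[1:] != s[:-1], True]
    return s[last], ctp[last], cfp[last], float((w * y).sum()), float((w * (1 - y)).sum())


def roc_curve(units: pd.DataFrame, weights=None, level: str | None = None) -> CurveResult:
    """Weighted ROC curve, trapezoidal area.

    The sweep visits each distinct observed score as a threshold; ties
    contribute a single vertex, so the trapezoidal area equals the weighted
    concordance statistic (ties counted one half) exactly.
    """
    thr, ctp, cfp, pos, neg = _sweep(units, weights)
    if pos <= 0:
        raise ValueError("ROC curve undefined: no positive units (with positive weight)")
    if neg <= 0:
        raise ValueError("ROC curve undefined: no negative units (with positive weight)")
    tpr = np.r_[0.0, ctp / pos]
    fpr = np.r_[0.0, cfp / neg]
    area = float(np.trapezoid(tpr, fpr))
    pts = np.column_stack([fpr, tpr])
    return CurveResult(points=pts, thresholds=thr, area=area, kind="roc", level=level)


def pr_curve(units: pd.DataFrame, weights=None, level: str | None = None) -> CurveResult:
    """Weighted precision-recall curve; area by the step sum.

    The area is ``sum_i (R_i - R_{i-1}) * P_i`` over the descending-threshold
    sweep, without linear interpolation between points (interpolating
    precision is optimistic).  The rightmost point has recall 1 and precision
    equal to prevalence.
    """
    thr, ctp, cfp, pos, _neg = _sweep(units, weights)
    if pos <= 0:
        raise ValueError("PR curve undefined: no positive units (with positive weight)")
    recall = ctp / pos
    precision = ctp / (ctp + cfp)
    dr = np.diff(np.r_[0.0, recall])
    area = float(np.sum(dr * precision))
    pts = np.column_stack([recall, precision])
    return CurveResult(points=pts, thresholds=thr, area=area, kind="pr", level=level)


@dataclass(frozen=True)
class ThresholdMetrics:
    """Confusion-matrix metrics at one threshold.

    ``ppv``/``npv``/``f1`` are None — an explicitly undefined state, never
    0 — when the corresponding denominator is empty (e.g. no predicted
    positives above the top score).
    """

    threshold: float
    sensitivity: float
    specificity: float
    ppv: float | None
    npv: float | None
    f1: float | None
    tp: float
    fp: float
    tn: float
    fn: float


def metrics_at_threshold(
    units: pd.DataFrame, threshold: float, weights=None
) -> ThresholdMetrics:
    """Weighted confusion counts and derived metrics at ``score >= threshold``."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must lie in [0, 1], got {threshold}")
    s, y, w = _scores_labels_weights(units, weights)
    pred = s >= threshold
    tp = float(w[pred & (y == 1)].sum())
    fp = float(w[pred & (y == 0)].sum())
    fn = float(w[~pred & (y == 1)].sum())
    tn = float(w[~pred & (y == 0)].sum())
    sens = tp / (tp + fn) if tp + fn > 0 else math.nan
    spec = tn / (tn + fp) if tn + fp > 0 else math.nan
    ppv = tp / (tp + fp) if tp + fp > 0 else None
    npv = tn / (tn + fn) if tn + fn > 0 else None
    f1 = (
        2.0 * ppv * sens / (ppv + sens)
        if ppv is not None and ppv + sens > 0
        else None
    )
    return ThresholdMetrics(
        threshold=threshold, sensitivity=sens, specificity=spec,
        ppv=ppv, npv=npv, f1=f1, tp=tp, fp=fp, tn=tn, fn=fn,
    )


@dataclass(frozen=True)
class ThresholdSelection:
    """The observed threshold nearest a target sensitivity."""

    threshold: float
    sensitivity: float
    specificity: float


def threshold_for_sensitivity(
    units: pd.DataFrame, target_sensitivity: float, weights=None
) -> ThresholdSelection:
    """Observed threshold whose achieved sensitivity is closest to target.

    Candidates are the distinct observed scores (the only thresholds at
    which the metrics change under the ``>=`` rule).  Ties in closeness are
    broken toward higher specificity, then toward the higher threshold.
    """
    if not 0.0 < target_sensitivity < 1.0:
        raise ValueError(
            f"target sensitivity must lie strictly in (0, 1), got {target_sensitivity}"
        )
    thr, ctp, cfp, pos, neg = _sweep(units, weights)
    if pos <= 0:
        raise ValueError("no positive units: sensitivity is undefined")
    sens = ctp / pos
    spec = 1.0 - cfp / neg if neg > 0 else np.zeros_like(cfp)
    gap = np.abs(sens - target_sensitivity)
    # lexicographic: smallest gap, then highest specificity, then highest threshold
    best = sorted(range(len(thr)), key=lambda i: (gap[i], -spec[i], -thr[i]))[0]
    return ThresholdSelection(
        threshold=float(thr[best]),
        sensitivity=float(sens[best]),
        specificity=float(spec[best]),
    )


def stratum_weighted_prevalence(
    stratum_counts: Mapping[str, tuple[float, float]],
    target_weights: Mapping[str, float],
) -> float:
    """Prevalence reweighted to target stratum shares.

    ``sum_s w_s * pos_s / total_s`` over strata — the deterministic analogue
    of resampling an oversampled validation set back to population mixture.
    """
    total_w = float(sum(target_weights.values()))
    if not math.isclose(total_w, 1.0, abs_tol=1e-9):
        raise ValueError(f"target weights must sum to 1, got {total_w}")
    if set(stratum_counts) != set(target_weights):
        raise ValueError(
            f"strata mismatch: counts for {sorted(map(str, stratum_counts))}, "
            f"weights for {sorted(map(str, target_weights))}"
        )
    out = 0.0
    for s, (pos, tot) in stratum_counts.items():
        if tot <= 0:
            raise ValueError(f"stratum {s!r} has non-positive total {tot}")
        out += target_weights[s] * (pos / tot)
    return out
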