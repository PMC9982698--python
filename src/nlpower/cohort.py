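"""Synthetic EHR cohort generator: patients -> notes -> scored passages.

Emulates the structure of a trial validation sample for a documented-outcome
classifier: a patient stratum oversampled relative to the trial (ADRD-like,
50% of the validation sample versus 11% of enrolment), per-stratum
patient-level outcome prevalence around a third, notes timestamped inside a
30-day post-randomization window, and passage scores drawn from a positive
and a negative distribution whose overlap is calibrated to a target AUC.
No text is generated — the atoms are scored, labeled, time-stamped passage
records, which is all the evaluation and planning modules consume.

Defaults mirror the validation-sample shape: 159 patients, 50/50 strata with
prevalences 25/80 and 29/79, ~15.6 notes per patient, ~10 passages per note,
passage-score separation targeting AUC 0.962.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.integrate import quad
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import beta as beta_dist
from scipy.stats import norm

from .design import ClassifierPerformance

__all__ = [
    "CohortConfig",
    "ScoreSeparation",
    "calibrate_score_separation",
    "empirical_auc",
    "generate_cohort",
    "inject_measurement_error",
]

logger = logging.getLogger(__name__)

# Fixed negative-score shape for the beta family: mass piled near zero, a
# thin upper tail standing in for confusable content (e.g. code-status talk).
_NEG_BETA = (1.2, 10.0)
_POS_CONC = 6.0  # concentration of the positive beta; its mean is calibrated


@dataclass(frozen=True)
class ScoreSeparation:
    """Resolved positive/negative score distributions for a target AUC."""

    target_auc: float
    family: str
    resolved_parameters: dict

    def sample(self, rng: np.random.Generator, size: int, positive: bool) -> np.ndarray:
        p = self.resolved_parameters["positive" if positive else "negative"]
        if self.family == "beta":
            return rng.beta(p["a"], p["b"], size=size)
        if self.family == "logit-normal":
            return expit(rng.normal(p["mu"], p["sigma"], size=size))
        raise ValueError(f"unknown score family {self.family!r}")


def _beta_auc(m: float) -> float:
    """P(pos > neg) for pos ~ Beta(c*m, c*(1-m)), neg ~ the fixed negative."""
    a_n, b_n = _NEG_BETA
    a_p, b_p = _POS_CONC * m, _POS_CONC * (1.0 - m)
    f = lambda x: beta_dist.cdf(x, a_n, b_n) * beta_dist.pdf(x, a_p, b_p)
    val, _err = quad(f, 0.0, 1.0, limit=200)
    return val


def calibrate_score_separation(target_auc: float, family: str = "beta") -> ScoreSeparation:
    """Solve the score-distribution separation achieving a target passage AUC.

    For the continuous families here ties have probability zero, so the
    calibration condition is simply ``P(positive score > negative score) =
    target``.  A target of exactly 0.5 returns identical distributions (zero
    separation); 1.0 is unattainable for overlapping continuous families and
    is rejected.
    """
    if not 0.5 <= target_auc < 1.0:
        raise ValueError(
            f"target AUC must lie in [0.5, 1); got {target_auc} "
            "(1.0 is unattainable for overlapping continuous score distributions)"
        )
    if family == "beta":
        a_n, b_n = _NEG_BETA
        if target_auc == 0.5:
            pos = {"a": a_n, "b": b_n}
        else:
            m_lo, m_hi = a_n / (a_n + b_n), 0.999
            hi = _beta_auc(m_hi)
            if target_auc > hi:
                raise ValueError(
                    f"target AUC {target_auc} unattainable in the beta family "
                    f"(maximum ~{hi:.4f})"
                )
            m = brentq(lambda x: _beta_auc(x) - target_auc, m_lo, m_hi, xtol=1e-10)
            pos = {"a": _POS_CONC * m, "b": _POS_CONC * (1.0 - m)}
        params = {"positive": pos, "negative": {"a": a_n, "b": b_n}}
    elif family == "logit-normal":
        # AUC of two unit-variance normals shifted by d is Phi(d / sqrt(2)),
        # and the logistic transform is monotone, so d has a closed form.
        d = math.sqrt(2.0) * float(norm.ppf(target_auc))
        params = {
            "positive": {"mu": d, "sigma": 1.0},
            "negative": {"mu": 0.0, "sigma": 1.0},
        }
    else:
        raise ValueError(f"unknown score family {family!r}")
    return ScoreSeparation(target_auc=target_auc, family=family, resolved_parameters=params)


def empirical_auc(sep: ScoreSeparation, n: int = 100_000, seed: int | None = None) -> float:
    """Monte Carlo check of a calibrated separation: rank AUC on n/n draws."""
    rng = np.random.default_rng(seed)
    pos = sep.sample(rng, n, positive=True)
    neg = sep.sample(rng, n, positive=False)
    # rank-statistic AUC via sorting, O(n log n)
    scores = np.concatenate([pos, neg])
    labels = np.concatenate([np.ones(n), np.zeros(n)])
    order = np.argsort(scores, kind="stable")
    ranks = np.empty_like(order, dtype=float)
    ranks[order] = np.arange(1, 2 * n + 1)
    # midranks for ties
    s_sorted = scores[order]
    ties = np.r_[True, s_sorted[1:] != s_sorted[:-1]]
    grp = np.cumsum(ties) - 1
    sums = np.bincount(grp, weights=ranks[order])
    counts = np.bincount(grp)
    mid = sums / counts
    ranks[order] = mid[grp]
    r_pos = ranks[labels == 1].sum()
    return float((r_pos - n * (n + 1) / 2) / (n * n))


def _sample_count(rng: np.random.Generator, spec: tuple, size: int) -> np.ndarray:
    """Sample a count distribution spec: ("poisson", {mean, shift?}) or ("fixed", {value})."""
    name, params = spec
    if name == "poisson":
        shift = int(params.get("shift", 0))
        out = rng.poisson(float(params["mean"]), size=size) + shift
    elif name == "fixed":
        out = np.full(size, int(params["value"]))
    else:
        raise ValueError(f"unknown count distribution {name!r}")
    return out


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of the synthetic cohort.

    ``arm_effect`` (optional) adds a risk difference to the intervention
    arm's per-stratum outcome prevalence, for end-to-end power experiments.
    """

    n_patients: int = 159
    stratum_fractions: Mapping[str, float] = field(
        default_factory=lambda: {"ADRD": 0.5, "non-ADRD": 0.5}
    )
    patient_prevalence: Mapping[str, float] = field(
        default_factory=lambda: {"ADRD": 25 / 80, "non-ADRD": 29 / 79}
    )
    notes_per_patient: tuple = ("poisson", {"mean": 14.6, "shift": 1})
    passages_per_note: tuple = ("poisson", {"mean": 9.0, "shift": 1})
    true_passages_per_positive_patient: tuple = ("poisson", {"mean": 4.0, "shift": 1})
    target_auc: float = 0.962
    score_family: str = "beta"
    window_days: int = 30
    arm_effect: float | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ValueError(f"n_patients must be >= 0, got {self.n_patients}")
        tot = float(sum(self.stratum_fractions.values()))
        if not math.isclose(tot, 1.0, abs_tol=1e-9):
            raise ValueError(f"stratum fractions must sum to 1, got {tot}")
        if set(self.patient_prevalence) != set(self.stratum_fractions):
            raise ValueError("patient_prevalence strata must match stratum_fractions")
        for s, p in self.patient_prevalence.items():
            hi = p + (self.arm_effect or 0.0)
            if not 0.0 <= p <= 1.0 or not 0.0 <= hi <= 1.0:
                raise ValueError(
                    f"prevalence for stratum {s!r} (with arm_effect) outside [0, 1]"
                )
        if self.window_days < 0:
            raise ValueError("window_days must be >= 0")

    @classmethod
    def from_dict(cls, d: Mapping) -> "CohortConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown cohort config field(s): {sorted(unknown)}")
        d = dict(d)
        for key in ("notes_per_patient", "passages_per_note", "true_passages_per_positive_patient"):
            if key in d and isinstance(d[key], (list, tuple)):
                d[key] = (d[key][0], dict(d[key][1]))
        return cls(**d)


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Sample one cohort of scored passage records, deterministically by seed.

    Sampling is top-down: stratum -> arm -> patient outcome -> note count ->
    passage counts -> which passages carry the true label -> scores -> note
    day offsets (uniform integers on [0, window]).  Every truly-positive
    patient is guaranteed at least one gold-positive passage; infeasible
    draws (more true passages requested than exist) are redrawn and the
    redraw count logged, never silently truncated.

    Returns a DataFrame with columns patient_id, note_id, passage_id,
    day_offset, score, gold_label, stratum, arm.
    """
    rng = np.random.default_rng(config.seed)
    cols = ["patient_id", "note_id", "passage_id", "day_offset",
            "score", "gold_label", "stratum", "arm"]
    n = config.n_patients
    if n == 0:
        return pd.DataFrame({c: [] for c in cols})

    sep = calibrate_score_separation(config.target_auc, config.score_family)

    strata = list(config.stratum_fractions)
    strat = rng.choice(strata, size=n, p=[config.stratum_fractions[s] for s in strata])
    arm = rng.permutation(np.r_[np.zeros(n // 2, dtype=int), np.ones(n - n // 2, dtype=int)])
    prev = np.array([config.patient_prevalence[s] for s in strat])
    if config.arm_effect is not None:
        prev = prev + config.arm_effect * (arm == 1)
    outcome = rng.random(n) < prev

    n_notes = _sample_count(rng, config.notes_per_patient, n)
    redraws = 0
    for i in np.nonzero(outcome & (n_notes == 0))[0]:
        while n_notes[i] == 0:
            n_notes[i] = _sample_count(rng, config.notes_per_patient, 1)[0]
            redraws += 1

    rows: list[dict] = []
    width = len(str(n))
    for i in range(n):
        pid = f"P{i + 1:0{width}d}"
        notes = int(n_notes[i])
        n_pass = _sample_count(rng, config.passages_per_note, notes) if notes else np.array([], int)
        total = int(n_pass.sum())
        gold = np.zeros(total, dtype=int)
        if outcome[i]:
            k = int(_sample_count(rng, config.true_passages_per_positive_patient, 1)[0])
            while k > total or k < 1:
                k = int(_sample_count(rng, config.true_passages_per_positive_patient, 1)[0])
                redraws += 1
            gold[rng.choice(total, size=k, replace=False)] = 1
        scores = np.where(
            gold == 1,
            sep.sample(rng, total, positive=True),
            sep.sample(rng, total, positive=False),
        )
        days = rng.integers(0, config.window_days + 1, size=notes)
        k = 0
        for j in range(notes):
            nid = f"{pid}-N{j + 1:03d}"
            for q in range(int(n_pass[j])):
                rows.append(
                    {
                        "patient_id": pid,
                        "note_id": nid,
                        "passage_id": f"{nid}-S{q + 1:03d}",
                        "day_offset": int(days[j]),
                        "score": float(scores[k]),
                        "gold_label": int(gold[k]),
                        "stratum": strat[i],
                        "arm": int(arm[i]),
                    }
                )
                k += 1
    if redraws:
        logger.info("generate_cohort: %d redraw(s) to satisfy construction guarantees", redraws)
    return pd.DataFrame(rows, columns=cols)


def inject_measurement_error(
    true_outcomes: np.ndarray,
    perf: ClassifierPerformance,
    seed: int | None = None,
) -> np.ndarray:
    """Flip binary outcomes through a nondifferential classifier.

    Each 1 is kept with probability *sensitivity*; each 0 becomes 1 with
    probability *1 - specificity*.  The Devine map gives the expected
    observed prevalence.
    """
    y = np.asarray(true_outcomes, dtype=int)
    rng = np.random.default_rng(seed)
    u = rng.random(y.shape)
    return np.where(y == 1, (u < perf.sensitivity), (u < 1.0 - perf.specificity)).astype(int)
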