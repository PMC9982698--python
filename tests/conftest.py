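import numpy as np
import pandas as pd
import pytest

from nlpower import CohortConfig, TrialDesign, generate_cohort


@pytest.fixture(scope="session")
def trial_design() -> TrialDesign:
    """The reference two-arm design: 1256/arm, p1=0.335, alpha 0.05, power 0.80."""
    return TrialDesign(n1=1256, n2=1256, p1=0.335, alpha=0.05, target_power=0.80)


def make_passages(rows):
    """Build a passage frame from (patient, note, passage, day, score, gold) tuples."""
    return pd.DataFrame(
        rows,
        columns=["patient_id", "note_id", "passage_id", "day_offset", "score", "gold_label"],
    ).assign(stratum="all")


@pytest.fixture(scope="session")
def validation_like_cohort() -> pd.DataFrame:
    """A validation-sample-shaped synthetic cohort (159 patients, 50/50 strata)."""
    return generate_cohort(CohortConfig(seed=20230302))


@pytest.fixture(scope="session")
def small_cohort() -> pd.DataFrame:
    """A smaller cohort for sweep-style properties."""
    cfg = CohortConfig(
        n_patients=60,
        notes_per_patient=("poisson", {"mean": 4.0, "shift": 1}),
        passages_per_note=("poisson", {"mean": 3.0, "shift": 1}),
        seed=11,
    )
    return generate_cohort(cfg)


def rank_auc_oracle(scores_pos, scores_neg, w_pos=None, w_neg=None) -> float:
    """Brute-force weighted concordance over all positive-negative pairs.

    Ties count one half.  O(n_pos * n_neg); the independent oracle for the
    trapezoidal ROC area.
    """
    sp = np.asarray(scores_pos, float)
    sn = np.asarray(scores_neg, float)
    wp = np.ones_like(sp) if w_pos is None else np.asarray(w_pos, float)
    wn = np.ones_like(sn) if w_neg is None else np.asarray(w_neg, float)
    num = 0.0
    for s, w in zip(sp, wp):
        num += np.sum(wn * ((s > sn) + 0.5 * (s == sn)) * w)
    return float(num / (wp.sum() * wn.sum()))
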