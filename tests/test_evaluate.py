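"""Hierarchical classifier evaluation: aggregation, ROC/PR, thresholds, reweighting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nlpower import (
    aggregate,
    metrics_at_threshold,
    pr_curve,
    roc_curve,
    stratum_weighted_prevalence,
    stratum_weights,
    threshold_for_sensitivity,
)

from conftest import make_passages, rank_auc_oracle


def units_from_scores(pos, neg):
    n = len(pos) + len(neg)
    return pd.DataFrame(
        {
            "unit_id": [f"u{i}" for i in range(n)],
            "score": list(pos) + list(neg),
            "gold_label": [1] * len(pos) + [0] * len(neg),
            "stratum": "all",
            "weight": 1.0,
        }
    )


class TestAggregate:
    def test_max_score_and_union_label(self):
        df = make_passages(
            [
                ("p1", "n1", "s1", 0, 0.1, 0),
                ("p1", "n1", "s2", 0, 0.9, 1),
                ("p1", "n2", "s1", 3, 0.3, 0),
            ]
        )
        pat = aggregate(df, "patient")
        assert len(pat) == 1
        assert pat.loc[0, "score"] == 0.9 and pat.loc[0, "gold_label"] == 1

    def test_single_passage_note_is_identity(self):
        df = make_passages([("p1", "n1", "s1", 2, 0.42, 1)])
        note = aggregate(df, "note")
        assert note.loc[0, "score"] == 0.42 and note.loc[0, "gold_label"] == 1

    def test_all_negative_notes_stay_negative(self):
        df = make_passages(
            [("p1", "n1", "s1", 0, 0.2, 0), ("p1", "n2", "s1", 5, 0.7, 0)]
        )
        pat = aggregate(df, "patient")
        assert pat.loc[0, "score"] == 0.7 and pat.loc[0, "gold_label"] == 0

    def test_note_level_keeps_notes_separate(self):
        df = make_passages(
            [("p1", "n1", "s1", 0, 0.2, 0), ("p1", "n2", "s1", 5, 0.7, 1)]
        )
        notes = aggregate(df, "note")
        assert len(notes) == 2
        assert sorted(notes["gold_label"]) == [0, 1]

    def test_idempotent_at_patient_level(self, small_cohort):
        once = aggregate(small_cohort, "patient")
        twice = aggregate(once, "patient")
        pd.testing.assert_frame_equal(
            once[["unit_id", "score", "gold_label", "stratum"]],
            twice[["unit_id", "score", "gold_label", "stratum"]],
        )

    def test_conflicting_stratum_rejected(self):
        df = make_passages([("p1", "n1", "s1", 0, 0.2, 0), ("p1", "n2", "s1", 1, 0.3, 0)])
        df.loc[1, "stratum"] = "other"
        with pytest.raises(ValueError, match="conflicting stratum.*p1"):
            aggregate(df, "patient")

    def test_roster_adds_noteless_patients_as_negatives(self):
        df = make_passages([("p1", "n1", "s1", 0, 0.8, 1)])
        roster = pd.DataFrame({"patient_id": ["p1", "p2"], "stratum": ["all", "all"]})
        pat = aggregate(df, "patient", roster=roster)
        assert len(pat) == 2
        row = pat[pat["patient_id"] == "p2"].iloc[0]
        assert row["score"] == 0.0 and row["gold_label"] == 0


class TestROC:
    def test_perfect_separation(self):
        assert roc_curve(units_from_scores([0.8, 0.9], [0.1, 0.2])).area == 1.0

    def test_all_ties_give_half(self):
        assert roc_curve(units_from_scores([0.5, 0.5], [0.5, 0.5])).area == pytest.approx(0.5)

    def test_hand_enumerated_concordance(self):
        # pairs: (.9,.6)=1 (.9,.1)=1 (.4,.6)=0 (.4,.1)=1 -> 3/4
        assert roc_curve(units_from_scores([0.9, 0.4], [0.6, 0.1])).area == pytest.approx(0.75)

    def test_endpoints(self):
        curve = roc_curve(units_from_scores([0.9, 0.4], [0.6, 0.1]))
        assert tuple(curve.points[0]) == (0.0, 0.0)
        assert tuple(curve.points[-1]) == (1.0, 1.0)

    def test_single_class_error_names_missing_class(self):
        with pytest.raises(ValueError, match="no negative"):
            roc_curve(units_from_scores([0.9], []))
        with pytest.raises(ValueError, match="no positive"):
            roc_curve(units_from_scores([], [0.1]))

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_trapezoid_equals_rank_statistic(self, seed):
        rng = np.random.default_rng(seed)
        n_pos, n_neg = rng.integers(1, 100, 2)
        # coarse score grid forces ties
        pos = rng.choice(np.linspace(0, 1, 12), n_pos)
        neg = rng.choice(np.linspace(0, 1, 12), n_neg)
        got = roc_curve(units_from_scores(pos, neg)).area
        assert got == pytest.approx(rank_auc_oracle(pos, neg), abs=1e-12)

    def test_weighted_auc_matches_weighted_oracle_and_sklearn(self):
        rng = np.random.default_rng(4)
        pos = rng.choice(np.linspace(0, 1, 8), 30)
        neg = rng.choice(np.linspace(0, 1, 8), 50)
        wp, wn = rng.uniform(0.5, 2.0, 30), rng.uniform(0.5, 2.0, 50)
        units = units_from_scores(pos, neg)
        w = np.r_[wp, wn]
        got = roc_curve(units, weights=w).area
        assert got == pytest.approx(rank_auc_oracle(pos, neg, wp, wn), abs=1e-12)
        from sklearn.metrics import roc_auc_score

        ref = roc_auc_score(units["gold_label"], units["score"], sample_weight=w)
        assert got == pytest.approx(ref, abs=1e-10)


class TestPR:
    def test_perfect_separation(self):
        assert pr_curve(units_from_scores([0.8, 0.9], [0.1, 0.2])).area == 1.0

    def test_constant_scores_give_prevalence(self):
        curve = pr_curve(units_from_scores([0.5] * 3, [0.5] * 7))
        assert curve.area == pytest.approx(0.3)

    def test_hand_enumerated_step_sum(self):
        # sweep .9/.6/.4/.1: contributions .5*1 + 0 + .5*(2/3) + 0 = 5/6
        curve = pr_curve(units_from_scores([0.9, 0.4], [0.6, 0.1]))
        assert curve.area == pytest.approx(5 / 6)

    def test_rightmost_precision_is_prevalence(self, small_cohort):
        units = aggregate(small_cohort, "note")
        curve = pr_curve(units)
        assert curve.points[-1, 0] == pytest.approx(1.0)
        assert curve.points[-1, 1] == pytest.approx(units["gold_label"].mean())

    def test_no_positives_is_an_error(self):
        with pytest.raises(ValueError, match="no positive"):
            pr_curve(units_from_scores([], [0.3, 0.4]))


class TestThresholdMetrics:
    def test_threshold_zero_flags_everything(self):
        m = metrics_at_threshold(units_from_scores([0.9, 0.2], [0.5]), 0.0)
        assert m.sensitivity == 1.0 and m.specificity == 0.0

    def test_threshold_above_max_score(self):
        m = metrics_at_threshold(units_from_scores([0.9], [0.5]), 0.95)
        assert m.sensitivity == 0.0 and m.specificity == 1.0
        assert m.ppv is None and m.f1 is None  # undefined, not zero

    def test_f1_is_harmonic_mean_of_published_row(self):
        # note-level row: sensitivity 70.1%, PPV 83.6% -> F1 0.76
        se, ppv = 0.701, 0.836
        f1 = 2 * se * ppv / (se + ppv)
        assert round(f1, 2) == 0.76

    def test_counts_and_derived_metrics_consistent(self, small_cohort):
        units = aggregate(small_cohort, "note")
        m = metrics_at_threshold(units, 0.4)
        assert m.sensitivity == pytest.approx(m.tp / (m.tp + m.fn))
        assert m.ppv == pytest.approx(m.tp / (m.tp + m.fp))
        assert m.f1 == pytest.approx(2 * m.ppv * m.sensitivity / (m.ppv + m.sensitivity))
        assert m.tp + m.fp + m.tn + m.fn == pytest.approx(len(units))

    def test_unit_weights_reduce_to_unweighted(self, small_cohort):
        units = aggregate(small_cohort, "patient")
        m1 = metrics_at_threshold(units, 0.3)
        m2 = metrics_at_threshold(units, 0.3, weights=np.ones(len(units)))
        assert m1 == m2

    def test_monotone_threshold_sweep(self, small_cohort):
        units = aggregate(small_cohort, "note")
        thresholds = np.linspace(0, 1, 21)
        ms = [metrics_at_threshold(units, t) for t in thresholds]
        sens = [m.sensitivity for m in ms]
        spec = [m.specificity for m in ms]
        assert all(a >= b for a, b in zip(sens, sens[1:]))
        assert all(a <= b for a, b in zip(spec, spec[1:]))


class TestThresholdForSensitivity:
    def test_perfect_classifier_reports_achieved_sensitivity(self):
        sel = threshold_for_sensitivity(units_from_scores([0.8, 0.9], [0.1, 0.2]), 0.8)
        assert sel.sensitivity == 1.0 and sel.specificity == 1.0

    def test_order_statistic_enumeration(self):
        # 10 positives with distinct scores 0.1..1.0: target 0.70 is achieved
        # exactly at the 7th-highest positive score (0.4)
        pos = [round(0.1 * k, 1) for k in range(1, 11)]
        sel = threshold_for_sensitivity(units_from_scores(pos, [0.01]), 0.70)
        assert sel.threshold == pytest.approx(0.4)
        assert sel.sensitivity == pytest.approx(0.7)

    def test_nearest_on_known_order_statistics(self):
        # candidate sensitivities are 27/30, 28/30, 29/30, 1; the nearest to
        # 0.926 is 28/30 ~ 0.933, reached at threshold 0.3
        pos = [0.6 + 0.01 * k for k in range(27)] + [0.1, 0.2, 0.3]
        sel = threshold_for_sensitivity(units_from_scores(pos, [0.05]), 0.926)
        assert sel.sensitivity == pytest.approx(28 / 30)
        assert sel.threshold == pytest.approx(0.3)

    def test_ties_break_toward_higher_specificity(self):
        # both thresholds 0.8 and 0.3 reach sensitivity 1.0; higher threshold
        # keeps the negative out
        sel = threshold_for_sensitivity(units_from_scores([0.8], [0.3]), 0.9)
        assert sel.threshold == pytest.approx(0.8)
        assert sel.specificity == 1.0


class TestStratumReweighting:
    def test_published_patient_and_note_prevalences(self):
        pat = stratum_weighted_prevalence(
            {"ADRD": (25, 80), "non-ADRD": (29, 79)}, {"ADRD": 0.11, "non-ADRD": 0.89}
        )
        note = stratum_weighted_prevalence(
            {"ADRD": (113, 1248), "non-ADRD": (155, 1232)}, {"ADRD": 0.11, "non-ADRD": 0.89}
        )
        assert round(pat * 100, 1) == 36.1
        assert round(note * 100, 1) == 12.2

    def test_equal_strata_equal_weights(self):
        assert stratum_weighted_prevalence(
            {"a": (20, 100), "b": (40, 100)}, {"a": 0.5, "b": 0.5}
        ) == pytest.approx(0.3)

    def test_zero_total_stratum_rejected(self):
        with pytest.raises(ValueError, match="non-positive total"):
            stratum_weighted_prevalence({"a": (0, 0), "b": (1, 2)}, {"a": 0.5, "b": 0.5})

    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            stratum_weighted_prevalence({"a": (1, 2)}, {"a": 0.7})

    def test_unit_weights_reproduce_analytic_reweighting(self, validation_like_cohort):
        units = aggregate(validation_like_cohort, "patient")
        target = {"ADRD": 0.11, "non-ADRD": 0.89}
        w = stratum_weights(units, target)
        weighted_prev = float(np.average(units["gold_label"], weights=w))
        counts = {
            s: (grp["gold_label"].sum(), len(grp))
            for s, grp in units.groupby("stratum")
        }
        assert weighted_prev == pytest.approx(
            stratum_weighted_prevalence(counts, target), abs=1e-12
        )
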