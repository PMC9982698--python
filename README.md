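# nlpower

**Misclassification-adjusted power analysis and abstraction planning for
clinical trials whose binary outcome is measured by an imperfect text
classifier.**

Trials increasingly measure outcomes — such as whether a goals-of-care
discussion was documented in a patient's chart — by running an NLP
classifier over free-text electronic health records instead of paying for
exhaustive manual chart abstraction. A classifier with sensitivity *se* and
specificity *sp* misclassifies some outcomes, and when the error is
nondifferential (the same in both arms) it attenuates the observed effect:
a true proportion *p* is observed, in expectation, as

```
p̂ = se·p + (1 − sp)(1 − p)
```

so the observed risk difference shrinks by the factor *se + sp − 1* and the
study loses power. `nlpower` is the design-stage toolkit for this setting,
aimed at trial statisticians and clinical-NLP researchers. It provides:

- **Analytic power** (`nlpower.power`): two-proportion power with the
  observed-proportion correction applied to both arms, a solver for the
  *detectable risk difference* — the smallest true RD detectable at a target
  power — and the full detectable-RD surface over (se, sp) grids. Cells with
  *se + sp ≤ 1* (non-identifiable) carry explicit sentinel states.
- **Monte Carlo validation** (`nlpower.simulate`): seeded simulation that
  draws true outcomes binomially, pushes them through the classifier, and
  applies the Pearson χ² test; plus Bland–Altman agreement between simulated
  and calculated power.
- **Hierarchical classifier evaluation** (`nlpower.evaluate`): passage
  scores aggregate to notes and patients by maximum, gold labels by union;
  weighted ROC/AUC, precision–recall/AUPRC, threshold metrics, selection of
  thresholds nearest target sensitivities, and reweighting of an oversampled
  validation stratum (e.g. ADRD patients) to trial prevalence.
- **Screened-abstraction planning** (`nlpower.screening`): when humans
  review only classifier-flagged passages, specificity is 1 by construction
  but patient-level sensitivity can drop below the classifier's own (a truly
  positive patient whose true passages all score below threshold is missed
  even if false-positive passages are flagged). The module computes that
  screened sensitivity, the review workload under a
  first-confirmed-discussion-or-window-end stopping rule, and the resulting
  detectable RD per threshold, plus linear abstractor-hour/cost scaling.
- **Synthetic cohorts** (`nlpower.cohort`): a generator of scored, labeled,
  time-stamped passage hierarchies with calibrated score separation
  (target AUC), so the whole pipeline runs without any real clinical data.

## Worked example

The reference design throughout is a 2512-patient two-arm trial (1256 per
arm), control-arm prevalence 33.5%, two-sided α = 0.05, target power 80%.
With a perfect outcome measure the trial can detect a risk difference of
5.4%. Measuring the outcome with a classifier operating at sensitivity
82.5% / specificity 89.2%:

```
$ nlpower power detectable-rd --n1 1256 --n2 1256 --p1 0.335 --se 0.825 --sp 0.892
detectable RD (fraction): 0.075376
detectable RD (percent, reported): 7.6
```

The detectable RD grows from 5.4% to 7.6% — the cost of misclassification.
Screened human abstraction at 92.6% patient-level sensitivity (and
specificity 1) recovers most of it, to 5.7%.

The same numbers fall out of the library API:

```python
from nlpower import TrialDesign, ClassifierPerformance, solve_detectable_rd

design = TrialDesign(n1=1256, n2=1256, p1=0.335, alpha=0.05, target_power=0.80)
solve_detectable_rd(design, ClassifierPerformance(0.926, 1.0)).rd  # 0.056958
```

End-to-end on synthetic data — generate a validation-sample-shaped cohort
(159 patients, ADRD stratum oversampled to 50%, passage-score separation
calibrated to AUC 0.962), evaluate it, and plan screened abstraction:

```
$ nlpower generate --seed 7 --out cohort.csv
wrote cohort.csv: 24697 passages, 2439 notes, 159 patients (seed 7)

$ nlpower evaluate --passages cohort.csv --level patient \
      --weights "ADRD=0.11,non-ADRD=0.89"
patient-level AUC 0.967, AUPRC 0.944 over 159 units
  target 70%: threshold 0.6478, se 71.5%, sp 100.0%
  target 80%: threshold 0.6097, se 79.8%, sp 97.1%
  target 90%: threshold 0.5100, se 90.2%, sp 81.9%

$ nlpower plan-screening --passages cohort.csv --thresholds 0.1:0.9:0.1 \
      --n1 1256 --n2 1256 --p1 0.335 --out plan.csv
wrote plan.csv: 9 thresholds; detectable RD 5.4%..20.5%
```

Each row of `plan.csv` gives, for one screening threshold, the screened
patient-level sensitivity, the number of passages flagged, the number a
human would actually review under the stopping rule, and the detectable RD —
the sensitivity-versus-workload trade-off a study team uses to pick its
operating point.

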