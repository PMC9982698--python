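# Methods

This note documents the statistical model, the numerical conventions, and
the design choices behind `nlpower`, in the order a reader would meet them.

## Outcome misclassification model

A binary outcome with true per-arm proportions (p1, p2) is measured by a
classifier with sensitivity *se* and specificity *sp*, assumed
**nondifferential**: the same (se, sp) in both arms. Each subject's observed
outcome is then Bernoulli with

    p̂ = se·p + (1 − sp)(1 − p),

an affine map in p with slope se + sp − 1 and fixed point
(1 − sp)/(2 − se − sp). Three consequences drive the package:

- the observed risk difference is (se + sp − 1)(p2 − p1): attenuation;
- when se + sp ≤ 1 the map is non-increasing and the design problem is
  **non-identifiable** — the solver returns a sentinel status, never a number;
- because each subject is misclassified independently, the observed
  positive count per arm is exactly Binomial(n, p̂), which is what both the
  analytic and the Monte Carlo paths exploit.

Differential misclassification (arm-dependent se/sp) is out of scope.

## Analytic power and the detectable risk difference

Power of the two-sided level-α Pearson χ² test of equal proportions is
computed by the standard normal approximation, both rejection tails
included, no continuity correction. Two variance conventions are available
in `power_two_proportions(..., variance=...)`:

- `"unpooled"` (default): the alternative-hypothesis variance
  s₁² = p1q1/n1 + p2q2/n2 on both sides of the rejection boundary;
- `"pooled-null"`: pooled variance under H0, unpooled under H1.

They differ by well under a percentage point of power at trial-scale n.
The **unpooled form is the default because, combined with the grid
reporting convention below, it exactly reproduces the detectable risk
differences published for the reference design** (5.4% / 7.6% / 5.7% for
perfect measurement, se 82.5%/sp 89.2%, and se 92.6%/sp 1.0 at
n = 1256/arm, p1 = 0.335, α = 0.05, power 0.80); no other standard variant
tried (pooled-null, pooled-both, noncentral-χ², arcsine) does, under any
rounding rule. The pooled-null form is retained because it is the natural
analytic comparator for the simulation module, which applies the
pooled-variance χ² statistic.

`solve_detectable_rd` finds the root in δ of
power(p̂(p1), p̂(p1 + δ)) = target by Brent's method on (0, 1 − p1) to
absolute tolerance 1e-6; power is strictly increasing in δ for
identifiable classifiers, so the root is unique, and re-evaluating power at
the root returns the target to within 1e-6. If power never reaches the
target before p1 + δ = 1 the result is the sentinel `UNATTAINABLE`.

`detectable_rd_percent` applies the reporting convention of iterative
grid-search software — the smallest δ on a 0.1-percentage-point grid whose
power reaches the target, i.e. the continuous root rounded **up** to the
grid. This is the convention under which the published values above are
reproduced verbatim; the continuous root is always available alongside.

## Monte Carlo power

One replication draws true positive counts per arm from Binomial(n, p),
keeps each true positive with probability se, flips each true negative with
probability 1 − sp, and applies the Pearson χ² test (pooled variance, no
continuity correction — matching the analytic module's test convention) to
the observed 2×2 table at level α. All replications are vectorised; 10 000
replications of a 1256/arm trial take milliseconds. Correctness was checked
three ways during development: the vectorised statistic agrees with
`scipy.stats.chi2_contingency(correction=False)` to 1e-8 on sampled tables;
the rejection rate agrees with exact enumeration of the binomial outcome
grid; and at se = sp = 1 it tracks the analytic power across a δ sweep.

Conventions the underlying procedure leaves open, fixed here:

- **Degenerate tables** (an outcome margin of zero): counted as
  non-rejections and reported in `PowerEstimate.n_degenerate`.
- **RNG**: one `numpy.random.Generator` (PCG64) per simulation spec; grids
  spawn per-cell child seeds from the master seed via
  `numpy.random.SeedSequence.spawn` in row-major (performance, effect)
  order, so results are independent per cell and invariant to evaluation
  order or parallel chunking.
- **Uncertainty**: the Monte Carlo standard error is √(p̂(1−p̂)/reps);
  Bland–Altman agreement uses simulated − calculated differences, limits of
  agreement at mean ± 1.96 sample SD.

A caveat worth knowing: a band of ±3 MC SE around the *normal
approximation* is not a calibrated test of the simulation, because the
approximation itself is biased by up to ~0.5 pp against the exact χ² power
in low-specificity, low-power cells (exact enumeration, n = 1256/arm). At
10 000 replications that bias is about one MC SE, so occasional cells fall
outside such a band even for a perfectly correct simulation. Mean-level
(Bland–Altman) agreement is the robust summary.

## Hierarchical classifier evaluation

Passages are the classification atoms; notes and patients are what trials
count. Scores aggregate upward by **maximum**, gold labels by **union**
(logical OR); aggregation is idempotent, and a patient roster can add
patients with no notes in the window as score-0, label-0 negatives. The
decision rule everywhere is **score ≥ threshold ⇒ positive**, so threshold
sweeps visit exactly the distinct observed scores.

- ROC: trapezoidal area over the tie-merged sweep, which equals the
  weighted concordance statistic (ties one half) exactly — property-tested
  against a brute-force pair-counting oracle.
- Precision–recall: area by the step sum Σ(Rᵢ − Rᵢ₋₁)Pᵢ without linear
  interpolation (interpolated precision is optimistic); the rightmost point
  is (recall 1, precision = prevalence).
- Threshold metrics: weighted confusion counts; PPV/NPV/F1 are `None` —
  explicitly undefined, never 0 — when their denominator is empty.
- Threshold selection: the observed threshold whose sensitivity is nearest
  the target, ties broken toward higher specificity, then higher threshold.
- Stratum reweighting: a validation sample that oversamples a stratum
  (e.g. ADRD patients at 50% when the trial enrols 11%) is reweighted
  deterministically, each unit receiving target-share/observed-share; this
  is the expectation of resampling to the target mixture and is exactly
  consistent with the closed form Σ wₛ·posₛ/totalₛ.

## Screened human abstraction

Human review of flagged passages is modeled as perfectly accurate
(reviewer = gold): no false-positive patient survives review, so the
strategy's specificity is identically 1, and a patient is detected only if
some *gold-positive* passage scores at or above the threshold — which is
why screened patient-level sensitivity is bounded above by the classifier's
own sensitivity at the same threshold. Workload follows the stopping rule
"review flagged passages in chronological order until the first confirmed
positive, else all of them, within the observation window"; same-day ties
break deterministically by note id then passage id, a convention fixed here
because the rule's source leaves same-day ordering unspecified. The
trade-off table feeds each threshold's screened sensitivity (specificity 1)
back into the detectable-RD solver. Abstractor effort converts passage
counts to hours and cost by explicit linear rates; abstractor error and
fatigue are out of scope.

## Synthetic cohort generator

The generator emulates the *structure* of a trial validation sample, not
its text. Defaults (all overridable) are the validation-sample shape:
159 patients; two strata at 50/50 with the ADRD-like stratum oversampled
relative to an 11% trial share; per-stratum patient-level outcome
prevalences 25/80 and 29/79 (reweighted trial-mixture prevalence ≈ 36.1%);
truncated-Poisson notes per patient (mean ≈ 15.6) and passages per note
(mean 10 — a package choice for note-length passages; corpus-level
512-token splitting that yields far more fragments per note is not
modeled); 1 + Poisson(4) gold-positive passages per positive patient; note
timestamps uniform on a 30-day window (clinically, notes cluster early in
an admission; uniform is a simplification). Positive and negative passage
scores come from a calibrated two-distribution family:

- `"beta"` (default): negatives fixed at Beta(1.2, 10) — mass near zero
  with a thin upper tail standing in for confusable content — and the
  positive Beta mean solved by Brent's method on the exact integral
  ∫F_neg·f_pos so that P(positive > negative) equals the target AUC
  (default 0.962);
- `"logit-normal"`: unit-variance normals through the logistic, where the
  separation has the closed form d = √2·Φ⁻¹(AUC).

Calibration is verified by a 10⁵-draw rank-statistic AUC within ±0.01.
Construction guarantees: every truly positive patient gets ≥ 1 positive
passage; infeasible draws are redrawn and the redraw count logged, never
silently truncated; identical seeds give byte-identical output.

What passing tests on these cohorts do **not** show: real passage scores
are not exchangeable draws from two fixed distributions (difficulty varies
by note type and patient), real note timing is front-loaded, and real
strata can differ in score distributions, not just prevalence. Results on
synthetic cohorts validate the *machinery* — aggregation, sweeps,
stopping-rule accounting, seed discipline — not any claim about a
particular clinical corpus.

## Known limitations

- Normal-approximation power only; no exact unconditional methods.
- Nondifferential misclassification only; no covariates, clustering, or
  time-to-event outcomes.
- No confidence intervals on AUC/AUPRC (DeLong etc.) and no calibration
  analysis of the classifier's scores.
- Effort estimates are strictly linear in review units.
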