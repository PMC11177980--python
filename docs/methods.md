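# Methods

This note documents the models, defaults and design choices behind
`acsselect`, and what the synthetic experiments do and do not establish.

## Covariate schema

A patient is described by 23 covariates: age (years) and sex; ten
medical-history binaries (hypercholesterolemia, hypertension, current
smoker, diabetes, prior MI, angina, prior CABG, prior PCI, CAD, family
history of cardiovascular disease); eight presenting-symptom binaries; and
three ECG interpretations (ST elevation, ST depression, T-wave inversion),
each a per-lead {0,1} vector over 11 leads. The lead vectors expand to one
column per lead (`_L01..\_L11`), giving 53 flat feature columns. The leads
are labelled positionally because the schema does not name them. Outcomes
are an ACS indicator with subtype STEMI / NSTEMI / UA (subtype `NONE` iff
no ACS); the NSTE-ACS task counts NSTEMI and UA as positive and everything
else — including STEMI — as negative.

Missing covariates (CSV empty cells) are imputed with constants, default
−1 for age and 0 for binaries; both fills are arguments of
`impute_constant` since only "a constant" is conventionally specified for
this kind of pipeline.

## Synthetic cohort generator

The generator emulates the statistics a prehospital chest-pain analysis
needs, not any individual patient's physiology:

- **Marginals.** Two presets reproduce the development ("internal",
  n=1756) and temporally shifted deployment ("external", n=1127) cohort
  tables — e.g. hypertension 53% vs 71%, ST depression (any lead) 28% vs
  19%. Age is truncated normal: mean 61 (internal) / 60 (external),
  SD 15.5 — a printed spread of ±31 read as mean ± 2 SD — with a floor at
  21 years (the enrolment criterion).
- **ECG lead vectors.** Any-lead positivity is drawn at the preset rate;
  given positivity, the number of positive leads follows a truncated
  geometric distribution on {1..11} (p = 0.45, so 1–3 leads are typical)
  and the positive leads are placed uniformly at random. Published cohort
  tables report only any-lead summaries, so the within-vector structure is
  a modelling choice.
- **Outcome mechanism.** A latent linear risk score
  `s = Σ coef_j x_j` (age centred at the preset mean, ECG coefficients per
  positive lead) maps to `P(ACS) = logistic(b + s)`. The intercept `b` is
  calibrated by bisection on a fixed pilot sample of 200,000 covariate
  draws so the marginal prevalence hits the 20% target; the calibration is
  cached and independent of the cohort seed. Default coefficients put the
  strongest weight on ST-elevation leads (2.2 per lead), moderate weight on
  ST depression (0.9/lead), chest pain (1.4), and cardiac history (prior
  MI and CAD 1.0), and zero on the near-universal "other" symptom. The
  overall scale was chosen once so that the planted signal's oracle AUROC
  (latent score vs outcome) is ≈0.93, leaving a fitted model in the
  high-0.8s — the regime of interest for the selective-classification
  question.
- **Subtypes.** Given ACS, subtype is drawn from (STEMI, NSTEMI, UA) =
  (0.65, 0.20, 0.15), so marginal NSTE-ACS prevalence is 7% of cases at
  20% ACS. Subtype is conditionally independent of the covariates given
  ACS — a simplification; in reality STEMI correlates with ST elevation.
- **Missingness.** Completely at random: each patient has one uniformly
  chosen scalar covariate blanked with probability 1.5% (default), under
  the 2% bound such registries report. ECG lead entries are never blanked.
- **Troponin.** An ordinal band {0,1,2} drawn from conditional
  distributions given ACS (defaults (0.15, 0.35, 0.50) for cases,
  (0.85, 0.12, 0.03) for non-cases). It exists only for the HEART-score
  comparator; the tree model never sees it.

**What the generator does not emulate:** covariate–covariate correlation
beyond what the shared latent score induces (real comorbidities cluster),
informative missingness, troponin kinetics, vital signs, and any
within-patient ECG lead anatomy. Passing tests therefore establish that
the *pipeline* behaves correctly under a known mechanism — prevalence
control, coverage control, ordering of ablations, benefit of abstention —
not that the reported effect sizes transfer to real registries.

## Ensemble

Members are xgboost binary classifiers (histogram tree method, single
thread for determinism). Ensemble diversity comes from independent member
seeds (`base_seed + m`) and Bernoulli row subsampling; members are
exchangeable, which is all the uncertainty decomposition requires. With
M=1 the model uncertainty is identically zero and total equals data
uncertainty — the single-model predictive-entropy comparator is that
degenerate case. Training samples are weighted inversely to class
frequency (normalised to mean weight 1; 20% prevalence gives a 4:1
positive:negative weight ratio), with weights estimated from each fold's
own training data.

Hyperparameters: the full grid is learning rate {0.01, 0.1, 1.0} × depth
{1, 3, 6, 10} × subsample {0.25, 0.5, 0.75} (36 points) at 1000 boosting
rounds with M=10 members, default base seed 1419528. Grid search scores
each candidate by validation AUROC using a single-member fit (the search
compares hyperparameters, not ensemble size; configurable via
`search_members`), breaks ties toward smaller depth then smaller learning
rate, refits the winner at full ensemble size, and logs the whole trace.

`EnsembleConfig.reduced()` is the desk-scale profile used by the package's
own repeated experiments: 60 boosting rounds and a 2-point grid (learning
rate {0.1, 1.0}, depth 3, subsample 0.75). At n≈1700 this profile reaches
external AUROC ≈0.88 on default synthetic cohorts, the same regime as the
full profile, at a fraction of the cost; any study-scale claim should be
re-run with the full grid.

Hard labels use threshold 0.5 on the ensemble-mean probability, with
equality predicting positive. Because training is class-weighted, 0.5 on
the weighted scale roughly corresponds to a prevalence-matched threshold
on the unweighted scale. The threshold is an explicit argument everywhere
it matters.

## Uncertainty

Entropies are natural-log (nats), `0·ln 0 = 0`. Total uncertainty is the
entropy of the member-mean distribution; data uncertainty the mean member
entropy; model uncertainty the difference, which Jensen's inequality makes
nonnegative. Negative differences within 1e-9 are clipped as floating-point
noise; anything larger raises — it would indicate a bug, not data. For a
binary task total uncertainty is bounded by ln 2 ≈ 0.693.

## Selective classification

The cutoff is the empirical quantile of validation total uncertainty at
the coverage target (default 0.8), under the inverse-ECDF (lower)
convention: the smallest observed value whose ECDF reaches the target.
Filtering drops cases with uncertainty strictly greater than the cutoff
(equality retains). On exchangeable validation/test draws the expected
test coverage equals the target; under distribution shift (the external
preset) realised coverage drifts below it, which is itself diagnostic.
At coverage target 1.0 the protocol skips filtering outright (cutoff ln 2,
the binary entropy bound) rather than using the validation maximum, so
"no abstention" means exactly that even when a test case is more uncertain
than anything seen in validation.

The risk–coverage sweep drops the `f`-most-uncertain fraction of cases for
a grid of `f` and records the AUROC of the supplied scores on the
remainder; ties in uncertainty break by original case order, single-class
remainders yield missing values. The sweep accepts any score vector, so
HEAR/HEART comparators can be evaluated under the tree ensemble's
exclusion order.

## Evaluation protocol

5-fold stratified cross-validation on the internal cohort (stratified on
the task label, seeded). Per fold: 80% training portion, of which 10% is
split off (stratified) as validation for grid search and cutoff
estimation; metrics are computed on the fold's held-out internal slice and
on the entire external cohort. Selective metrics are computed on the
retained subset only; prevalence is always the evaluated subset's
empirical positive rate, reported because it drives PPV/NPV. Undefined
ratios (empty denominator) are recorded as missing and excluded from
aggregation with a warning, never imputed as zero. Aggregates are mean and
2× the standard error of the 5 fold values (2× SD available via
`dispersion="sd"`). A structural leakage guard asserts on every run that
no internal case appears in both a fold's training+validation and test
sets and that the external cohort never influences fitting or cutoff
estimation. The NSTE-ACS task refits from scratch on the relabelled
outcome rather than reusing ACS scores.

## Clinical score comparators

HEAR (0–8) and HEART (0–10) sum 0–2-point components. Bedside component
definitions involve clinical judgement not present in the covariate
schema, so components are proxied (see `clinical.py` docstring and the
editable mapping asset `data/heart_components.json`): age bands <45 /
45–64 / ≥65; risk-factor counts with atherosclerotic history forcing 2
points; ECG 2 points for ST changes, 1 for isolated T-wave inversion;
history proxied from chest pain ± autonomic symptoms; troponin band as the
troponin points. Scores are used as AUROC ranking statistics (ties count
½). These are comparators for the exclusion-order experiment, not
validated clinical instruments.

## Problem sizes and numerical choices

The package's repeated experiments (test suite and examples) use the
default cohort sizes 1756/1127 with the reduced ensemble profile, 20
seeds for the selective-benefit and ablation comparisons, and n=20,000
cohorts for calibration checks — sizes at which every quantity of interest
(prevalence to ±0.9%, coverage to ±2%, AUROC orderings) is resolved well
beyond the effects being tested. Quantile estimation uses the documented
inverse-ECDF convention; all stochastic stages consume explicit seeds
(the CLI fans a single global seed out per stage via CRC-32 hashing of
the stage name); xgboost runs single-threaded so results are bit-identical
across runs on a machine.

## Known limitations

- Synthetic covariates are conditionally independent given the latent
  score; effect sizes on real registries will differ.
- The HEAR/HEART component mapping is a proxy; comparisons against them
  are qualitative (direction of correlation with exclusion), not
  score-accurate.
- No probability calibration post-processing; reported probabilities are
  on the class-weighted scale.
- The ensemble approximates posterior sampling by seed + subsampling
  diversity; it does not implement stochastic-gradient-Langevin boosting
  internals.
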