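# Methods

This note documents the models and procedures implemented in `icuconsensus`,
the parameter choices behind the synthetic-data defaults, and what the
package's tests do and do not establish about real annotated ICU data.

## 1. The labelling problem

A panel of annotators independently grades patient records on a five-point
ordinal severity scale A–E (A ≈ stable, likely discharged within the hour;
E ≈ severe cardiovascular instability, at risk of death within the hour),
from six variables: adrenaline and noradrenaline infusion rates, FiO₂, SpO₂,
mean arterial pressure (MAP) and heart rate. One classifier is trained per
annotator; disagreement between annotators propagates into disagreement
between models and into degraded consensus models. The package quantifies
each link of that chain and implements learnability-filtered consensus as
the remedy.

Real panels of this kind are privacy-restricted, so all analyses here run on
synthetic data whose generator is itself a first-class, tested component.

## 2. Synthetic cohort model

Each patient carries a latent severity `z ∈ [0, 1]`. Features are monotone
noisy transforms of `z`, clipped to physiological ranges:

| feature | mean response | noise s.d. | range |
|---|---|---|---|
| adrenaline (µg/kg/min) | `0.6·(z − 0.25)` | 0.03 | [0, 2] |
| noradrenaline (µg/kg/min) | `0.9·z` | 0.04 | [0, 3] |
| FiO₂ | `0.21 + 0.60·z` | 0.03 | [0.21, 1] |
| SpO₂ (%) | `99 − 18·z` | 1.0 | [50, 100] |
| MAP (mmHg) | `92 − 40·z` | 3.0 | [30, 140] |
| HR (bpm) | `68 + 75·z` | 5.0 | [20, 220] |

Slopes and noise levels were chosen once so that (a) severity is recoverable
from the features well enough for a consistent annotator's labelling to be
highly learnable at 60 training records, while (b) enough irreducible noise
remains that learnability sits in a realistic 0.3–0.8 band rather than at 1.
Vasopressor doses use the standard ICU infusion convention (µg/kg/min); units
matter only internally.

**Trajectories.** A terminal severity `z_T ~ U(0, 1)` is drawn per patient;
the admission-side severity (5 h before outcome) is pulled toward the cohort
centre (`0.5 + 0.6(z_T − 0.5)` plus N(0, 0.1) patient spread), and the five
hourly values interpolate linearly between the two with AR(1) noise
(ρ = 0.5, innovation s.d. 0.03), clipped to [0, 1]. This is the simplest
dynamic that gives the temporal weighting something real to aggregate.

**Outcomes.** Patients whose final-hour severity reaches the cohort's 0.75
quantile die; those below the 0.25 quantile are discharged alive; the middle
band is indeterminate and never sampled into validation sets. This
guarantees separable discharge/death cohorts like a terminal-hour extract
from a real ICU database; with both quantiles set to the same value every
patient receives an outcome.

## 3. Annotator model

An annotator bands `z` into A–E at four strictly increasing thresholds
(default 0.2/0.4/0.6/0.8), corrupted by three mechanisms:

- **bias** — an additive shift of all thresholds (systematic over/under
  grading);
- **inconsistency rate δ** — with probability δ the judgement uses a
  reduced rule of thumb (banding the MAP-only severity proxy
  `(92 − MAP)/40`), emulating shortcut heuristics;
- **noise rate ε** — with probability ε the final label slips one category
  toward a neighbour (at A or E the slip is forced inward, so ε = 1 on pure
  band-A records yields all-B labels).

Adjacent-category slips, not uniform relabelling, are used because adjacent
confusion is the dominant clinical disagreement mode.

**Default panel (frozen).** Four consistent annotators (C1–C4: ε ≤ 0.03,
δ ≤ 0.02, |bias| ≤ 0.01, true thresholds) and seven noisy ones (C5–C11:
ε 0.30–0.50, δ 0.20–0.40, |bias| ≤ 0.07) with *extremity-averse* thresholds
(0.10/0.38/0.62/0.92), i.e. reluctance to assign A or E. The extremity
aversion is essential: purely symmetric slips would largely cancel under a
majority vote, whereas a systematic aversion to extreme categories both
degrades learnability and drags the majority-vote consensus away from the
extreme classes that the discharge/death validation actually tests. This
produces the mixed-learnability regime (scores straddling the 0.7 gate) the
consensus analysis is about.

## 4. Learnability and per-annotator models

Backends: decision tree (default), random forest, logistic regression, each
with a small fixed hyperparameter grid (tree depth {3, 5, ∞} ×
min-leaf {1, 3}; RF adds 100 trees; LR C ∈ {0.1, 1, 10}) selected by
cross-validated grid search maximising micro-F1, then refit on all rows.
The grid is deliberately small: reproducibility over exhaustiveness.

Learnability = the winning cell's cross-validated micro-F1 of each
annotator's model against that annotator's own labels. Within one
learnability report all annotators share a single unstratified 5-fold row
partition, so scores are directly comparable (stratification cannot be
shared across differing label columns). When a single annotator's model is
trained standalone, folds are stratified when every class has ≥ k members
and fall back to unstratified with a warning otherwise — 60-row panels with
rare E labels must not crash. A single-class label column yields a constant
predictor with learnability 1 (its CV accuracy), keeping panel pipelines
total. Micro-F1 equals accuracy for single-label multiclass output; the
identity is asserted per fold at fit time. Class weighting is off by
default and switchable to `balanced`; in this simulation it makes no
qualitative difference.

## 5. Agreement statistics

Cohen's κ (sklearn), Fleiss' κ (statsmodels, over category counts on the
declared A–E alphabet so unused categories stay comparable), and a
hand-implemented nominal Krippendorff's α via the coincidence matrix
(tolerating missing cells); α is cross-checked in the tests against an
independent brute-force pairwise-disagreement oracle. Degenerate perfect
agreement (p_e = 1, e.g. two identical constant raters) returns 1.0 with a
warning rather than 0/0. Interpretation scales: Cohen 0.0–0.20 None /
0.21–0.39 Minimal / 0.40–0.59 Weak / 0.60–0.79 Moderate / 0.80–0.90 Strong /
>0.90 Almost Perfect; Fleiss <0 Poor / 0.0–0.20 Slight / 0.21–0.40 Fair /
0.41–0.60 Moderate / 0.61–0.80 Substantial / >0.80 Almost Perfect.
Summaries can be stratified (e.g. by discharge outcome); strata with fewer
than two items are skipped with a warning. Agreement is computed on the
5-category labels by default; the 3-class grouping can be analysed by
passing grouped labels.

## 6. Consensus constructions

- **MV** fuses all annotators' training labels by per-item mode. Ties break
  to the most severe tied mode (clinically conservative, deterministic);
  least-severe and seeded-random rules are available.
- **TMV** restricts the vote to annotators with learnability strictly
  greater than the threshold (default 0.7; strict inequality, so exactly
  0.7 is excluded). An empty selection is a configuration error advising a
  lower threshold. With a single qualifying annotator their labels are used
  verbatim. MV/TMV labels then train an ordinary classifier ("consensus
  annotator").
- **FC / TFC** fuse *predictions*, not training labels: member models' A–E
  outputs are read as 1–5 ordinal confidences (1 = discharge within the
  hour, 5 = death within the hour) and averaged per record, excluding exact
  midpoint (3) outputs as "uncertain". An all-midpoint record returns 3.0.
  Confidences stay real-valued (rounding would destroy the confidence
  semantics); only exactly-3 member outputs are excluded, a near-3 averaged
  confidence is kept.

## 7. Validation

Ground truth exists only at the extremes: discharged-alive ⇒ CL1,
died ⇒ CL3, under the grouping CL1 = A, CL2 = B/C/D, CL3 = E. CL2
predictions are therefore wrong for every validation patient, and micro-F1
is computed on the grouped 3-class task (on which it equals accuracy).

Temporal validation weights the five hourly scores by (0.1, 0.1, 0.2, 0.3,
0.3) for hours 5…1 before outcome; the weights sum to 1 so the "weighted
sum" is also the weighted mean and stays in [1, 5]. Cut-off schemes map the
score to a class using the printed interval rules with a 1e-9 boundary
tolerance:

- Extreme: CL1 = 1, CL2 = (1, 4], CL3 = (4, 5] — CL1 requires exactly 1.0;
- Neutral: CL1 = [1, 3], CL2 = (3, 4), CL3 = [4, 5];
- Extreme(2): CL1 = [1, 2], CL2 = (2, 4), CL3 = [4, 5].

FC/TFC confidences feed the same machinery; on static sets they are mapped
through the chosen scheme directly (the discrete grouping is undefined for
real scores). The hourly-outcome model (`hourly_outcome_model`) additionally
fits a DT or LR on the per-patient vector of five hourly predictions against
the true outcome (5-fold grid search on micro-F1); the logistic backend
reports per-hour odds ratios exp(β) oriented toward the risk of death.

## 8. Orchestration and reproducibility

`run_experiment` executes simulate → train → agree → consensus → validate
from one serialisable config; each stage failure is reported with its stage
name. The master seed fans out to per-stage seeds via `SeedSequence.spawn`,
every output table carries a config-hash + seed header, and a rerun with
the same config is byte-identical. `replicate_experiment` repeats the run
across consecutive seeds and reports TMV-vs-MV win rates (ties are not
wins). Default problem sizes — 60-record panel, 1000-patient cohort,
100 + 100-patient validation sets, 10 replicate seeds — keep a full
replicate study under a couple of minutes on one CPU while leaving
sampling noise well below the effect sizes studied.

## 9. What the synthetic results do and do not show

The generator reproduces the *structure* of the study — heterogeneous
annotator consistency, extremity aversion, separable terminal outcomes,
5-hour trajectories — not the measured values of any real panel. Passing
tests establish that the statistics are computed correctly and that the
qualitative phenomena (learnability recovers annotator consistency;
learnability-gated consensus beats plain majority vote; fuzzy consensus is
competitive) hold in this controlled regime. They do not certify effect
sizes on real ICU data, where feature-severity relationships are not
monotone-Gaussian, annotations may depend on information outside the six
variables, outcomes are not severity-quantile-separable, and panels may be
incomplete. The FC/TFC scores here are near-ceiling because the synthetic
extremes are cleanly separable; real panels sit far lower.

Other known limitations: no missing-label modelling (panels are complete by
construction); no ordinal/weighted κ variants (the analysis is nominal); no
XGBoost/SVM backends; no probabilistic truth-inference (Dawid–Skene-style)
consensus — the repertoire is exactly MV/TMV/FC/TFC.
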