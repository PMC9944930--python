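# icuconsensus

Tools for studying — and coping with — **annotation inconsistency** in
clinical machine learning, in the setting of ICU patient-severity labelling.

When several senior clinicians independently label the same patients on an
ordinal severity scale, they disagree surprisingly often, through a mixture of
systematic bias, idiosyncratic judgment rules, and plain slips. Classifiers
trained on each expert's labels therefore disagree too, and a naive consensus
(majority vote over everyone) can bake the noise in. This package implements
the full analysis pipeline for quantifying that problem and for building
better consensus models, aimed at methods researchers in clinical ML and
biostatistics:

- **Synthetic study data.** Generators for an ICU severity-annotation panel
  (default: 60 patient records described by 6 clinical variables —
  adrenaline, noradrenaline, FiO₂, SpO₂, MAP, HR — each labelled A–E by 11
  simulated annotators of heterogeneous consistency) and for class-balanced
  validation sets of terminal 5-hour patient trajectories ending in discharge
  or death. Real annotated ICU panels of this kind are privacy-restricted, so
  the generators emulate their statistical structure from a latent-severity
  model with configurable bias / noise / rule-inconsistency per annotator.
- **Per-annotator models and learnability.** One grid-searched classifier
  (decision tree, random forest, or logistic regression) per annotator,
  scored by cross-validated micro-F1 *against that annotator's own labels*.
  This "learnability" measures how consistently an annotator's judgments
  follow from the recorded variables.
- **Agreement statistics.** Pairwise Cohen's κ, Fleiss' κ, and Krippendorff's
  α (nominal, missing-tolerant) with the standard verbal interpretation
  scales, overall and stratified by outcome.
- **Consensus constructions.** Majority Vote (MV); Top Majority Vote (TMV:
  majority vote over annotators with learnability > 0.7); Fuzzy Consensus
  (FC: member predictions read on the 1–5 ordinal scale and averaged,
  excluding "uncertain" midpoint outputs); and Top Fuzzy Consensus (TFC).
- **External validation.** Discharge-vs-death scoring of all models on static
  (last hour) and temporal (last 5 hours) validation sets, using the
  three-class grouping CL1 = A, CL2 = B/C/D, CL3 = E, hourly weights
  (0.1, 0.1, 0.2, 0.3, 0.3), and the Extreme / Neutral / Extreme(2) cut-off
  schemes for mapping weighted scores back to classes.

## The core quantities

For two raters with observed agreement $p_o$ and chance agreement $p_e$
(from the marginal label distributions), Cohen's
$\kappa = (p_o - p_e)/(1 - p_e)$; Fleiss' κ generalises this to many raters
via per-item category counts, and Krippendorff's
$\alpha = 1 - D_o/D_e$ compares observed to expected disagreement.

Learnability of annotator $m$ is the 5-fold cross-validated micro-F1 of a
classifier $f_m(\mathbf{x})$ trained on that annotator's labels (for
single-label multiclass prediction micro-F1 equals accuracy; the package
asserts this identity on every fold). TMV fuses only the label columns of
annotators with learnability strictly above 0.7.

For temporal validation, a patient's five hourly predictions
$y_5,\dots,y_1 \in [1,5]$ are combined as
$s = 0.1 y_5 + 0.1 y_4 + 0.2 y_3 + 0.3 y_2 + 0.3 y_1 \in [1,5]$
and mapped to CL1/CL2/CL3 by the chosen cut-off scheme.

## Worked example

```python
import icuconsensus as ic

panel = ic.generate_annotated_panel(60, seed=42)          # 60 records, 11 annotators
report = ic.assess_learnability(panel, ic.ModelSpec(seed=0))
summary = ic.agreement_summary(panel.labels)
print(f"mean pairwise Cohen kappa = {summary.mean_pairwise_kappa:.3f}"
      f" ({summary.interpretation['cohen']})")
print(f"Fleiss kappa = {summary.fleiss_kappa:.3f} ({summary.interpretation['fleiss']})")

cohort = ic.generate_cohort(1000, seed=7)
vset = ic.make_validation_sets(cohort, 100, 100, "static", seed=1)
mv = ic.ConsensusClassifier("MV", model_spec=ic.ModelSpec(seed=0)).fit(panel)
tmv = ic.ConsensusClassifier("TMV", model_spec=ic.ModelSpec(seed=0)).fit(panel, report)
print(ic.evaluate_static(mv, vset, model_id="MV"))
print(ic.evaluate_static(tmv, vset, model_id="TMV"))
```

prints

```
mean pairwise Cohen kappa = 0.338 (Minimal)
Fleiss kappa = 0.338 (Fair)
ValidationResult('MV', micro_f1=0.690, alive=78/100, dead=60/100, layout='static')
ValidationResult('TMV', micro_f1=0.825, alive=93/100, dead=72/100, layout='static')
```

The annotators' raw panel shows only minimal-to-fair agreement, and the
learnability-gated consensus (TMV, fusing the four internally consistent
annotators, here C1–C4 with scores 0.72–0.80) classifies discharge-vs-death
outcomes substantially better than the all-annotator majority vote, whose
training labels absorb the noisy majority's extremity-averse labelling.

A CLI mirrors the library (`icuconsensus report -o out/`,
`icuconsensus replicate -n 10 -o out/`, plus `simulate` / `train` / `agree` /
`consensus` / `validate` subcommands; see `icuconsensus --help`).

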