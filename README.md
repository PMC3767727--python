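# hybridcbr

Hybrid case-based reasoning for binary clinical prediction: a **soft
K-nearest-neighbour classifier whose similarity and label fusion are both
informed by a logistic regression model**, plus the simulation machinery to
study its robustness to irrelevant attributes.

## The problem

Case-based reasoning (CBR) systems solve a new case — here, predicting
whether an incident dialysis patient will be registered on the renal
transplant waiting list within a year — by retrieving the most similar
previously solved cases and reusing their outcomes. With a case base of
patients described by binary attributes (age group, comorbidities,
care-setting factors, ...), a plain K-NN treats every attribute and every
stored case as equally informative. Real case bases are not like that: a few
attributes dominate the outcome, some are pure noise, and some stored cases
fit the general pattern poorly.

This package couples the K-NN to a logistic regression (LR) fitted on the
training cases:

* **Attribute weights.** For a fitted model with coefficients β̂ₐ and
  standard errors σ̂ₐ, the Wald statistic Wₐ = (β̂ₐ/σ̂ₐ)² measures each
  attribute's evidential strength; normalized weights
  wₐ = Wₐ / Σₐ′ Wₐ′ enter a weighted Hamming similarity between cases
  p and q over the attribute set 𝒜:

      s(p, q) = 1 − Σₐ wₐ · XOR(pₐ, qₐ)  ∈ [0, 1].

  Attributes removed by backward stepwise selection (AIC) get weight 0.
* **Case weights.** Each solved case's Pearson residual
  rₚ = (yₚ − π̂ₚ)/√(π̂ₚ(1−π̂ₚ)) measures how far it sits from the LR
  archetype; its reliability weight is ωₚ = φ(|rₚ|), the standard normal
  density, maximal (1/√2π) for archetypal cases and decaying smoothly for
  outliers.
* **Soft K-NN.** For a query, the K most similar labeled cases are
  selected (ties broken by ascending case index) and their labels fused as
  ŷ = Σᵢ ω̃ᵢ yᵢ with fusion weights ω̃ renormalized to sum to one over the
  neighborhood — a score in [0, 1], not a hard class. K is tuned on a
  held-out *setting set*: the smallest K ≤ k_max maximizing the setting AUC.

Five variants are exposed for comparison: standalone `lr`, standalone `cbr`
(uniform weights), `cbr_wa` (attribute weighting), `cbr_wp` (case
weighting), and `cbr_wa_wp` (both — the method of interest). The headline
property, reproduced by the evaluation protocol on synthetic cohorts, is
that `cbr_wa_wp` barely loses AUC when 50 pure-noise attributes flood the
case base, while standalone LR and K-NN degrade markedly.

## Worked example

The original registry data are not public; the `synthetic` module generates
cohorts with the same structure (n = 1137 complete cases, 19 binary
attributes with one dominant predictor, ~23% outcome prevalence).

```python
from hybridcbr import HybridCBR, generate_case_base, rein_like_spec

cohort = generate_case_base(rein_like_spec(seed=3))
results = HybridCBR(cohort, variant="cbr_wa_wp", seed=1).fit()
print(results.summary())
report = results.evaluate(B=500, seed=5)
print(f"evaluation AUC: {report.auc_point:.3f}")
print(f"bootstrap mean: {report.auc_bootstrap_mean:.3f} "
      f"(95% CI {report.ci_low:.3f}-{report.ci_high:.3f}, B={report.n_bootstrap})")
```

which prints

```
Hybrid CBR results
==================
variant:            cbr_wa_wp
stepwise selection: False
split sizes:        train=379, setting=379, eval=379
logistic model:     19 attributes, AIC=365.24, converged=True
tuned K:            33  (setting AUC=0.730)

attribute                          coef      se  weight %
---------------------------------------------------------
age_lt_60                         2.122   0.323      59.3
hypertension                     -0.418   0.284       3.0
ischemic_heart_disease           -0.198   0.321       0.5
malignancy_history               -0.244   0.369       0.6
private_facility                  1.063   0.303      16.9
transplant_center_followup        0.737   0.287       9.0
employed                         -0.047   0.293       0.0
...

evaluation AUC: 0.771
bootstrap mean: 0.770 (95% CI 0.696-0.836, B=500)
```

The weight column is the normalized Wald share: the age indicator dominates
(59% here), a handful of care-related factors carry moderate weight, and the
null attributes are near zero — this is the profile the weighted similarity
exploits. The bootstrap report resamples the 379 evaluation cases B times
and gives the mean replicate AUC with its 2.5/97.5-percentile interval.

The three-way split (train / setting / evaluation) uses largest-remainder
rounding, so 1137 cases always split into exactly 379 + 379 + 379;
`homogeneity_check` runs per-attribute Pearson chi-squared tests to confirm
the parts are comparable.

## Command line

```bash
hybridcbr simulate --preset rein --n 1137 --noise 50 --seed 1 --out cohort.csv
hybridcbr predict --variant cbr_wa_wp --cohort cohort.csv --queries new.csv \
    --k auto --out scores.csv
hybridcbr protocol --preset rein --noise 50 --bootstrap 500 --seed 1 --out results/
```

`protocol` runs the full grid — five variants × {19-attribute clean, +50
noise attributes} × {all attributes, stepwise-selected attributes} — and
writes the AUC grid, the per-cell weight tables and a run manifest.

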