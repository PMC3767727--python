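# Methods

This note records the model, the estimation and tuning procedures, the
synthetic-cohort design, and the numerical choices made where the design was
genuinely open. It documents what the code computes; all empirical numbers
referenced here are produced by the test suite or `scripts/acceptance.py`.

## Model and decision process

A *case base* is an n × m matrix of binary attribute values (0/1, missing
allowed before filtering) with a binary outcome label per solved case. All
analyses are complete-case: rows with any missing value are removed first
(`filter_complete_cases`); no imputation is attempted.

The classifier is a **soft K-NN**: for a query case q it returns a score in
[0, 1] rather than a hard class (thresholding is deliberately out of scope).
Two learned weight families modify the plain K-NN:

1. **Similarity.** d(p, q) = Σₐ wₐ·XOR(pₐ, qₐ) and s = 1 − d, where the
   attribute weights wₐ ≥ 0 sum to one. With uniform weights this is the
   Hamming distance rescaled to [0, 1].
2. **Fusion.** The K most similar labeled cases are selected; the score is
   Σᵢ ω̃ᵢ yᵢ, where the fusion weights ω̃ are the neighbors' raw reliability
   weights renormalized to sum to one over the neighborhood (uniform 1/K in
   the unweighted variants). The score is therefore a convex combination of
   neighbor labels.

### Learning the weights

A logistic regression P(y=1|x) = expit(β₀ + Σₐ βₐxₐ) is fitted by maximum
likelihood on the training third (statsmodels, Newton scoring; convergence
at score tolerance 1e-10 within 100 iterations; standard errors from the
inverse observed information).

* Attribute weight: wₐ ∝ (β̂ₐ/σ̂ₐ)², the Wald chi-squared statistic, 0 for
  attributes not in the model. An unsquared |z| variant is available
  (`wald_squared=False`) for sensitivity analysis; the squared form is the
  default because it is the standard Wald statistic and yields the intended
  "percentage share" interpretation after normalization.
* Case weight: ωₚ = φ(|rₚ|) with rₚ the Pearson residual
  (yₚ − π̂ₚ)/√(π̂ₚ(1−π̂ₚ)) and φ the standard-normal density. ω is strictly
  positive and bounded by φ(0) = 1/√2π ≈ 0.399, so fusion weights are always
  well defined. Residual magnitudes are treated as roughly standard normal;
  only the ranking and relative decay matter for fusion.

Case weights are stored raw and renormalized **over the selected neighbors**
at fusion time, so the constraint "fusion weights sum to one" holds on the
neighbor set. Any global rescaling of the raw weights cancels in that
renormalization, so storing them raw loses nothing; pre-normalizing over the
whole training set would be an equivalent parameterization.

### Attribute selection

`stepwise_select` performs backward-only stepwise selection by AIC: starting
from the full model, repeatedly refit all single-attribute deletions and
remove the one lowering AIC most, until no deletion lowers AIC. There is no
forward re-entry. Candidate models are scanned with an internal Newton
solver (only the log-likelihood is needed); the surviving attribute set is
refitted through the standard path. The intercept is never a candidate.
Under the null (all βₐ = 0) each attribute is retained with probability
≈ P(χ²₁ > 2) ≈ 0.157; the test suite verifies this Monte-Carlo.

In the "selected attributes" sub-scenario the dropped attributes keep weight
exactly 0 in the similarity (both Wald and uniform weighting), which is
equivalent to projecting the case base onto the selected attributes but
simpler; a perturbation test verifies zero-weight attributes are bit-level
inert.

### K tuning

K is tuned on a dedicated *setting* third: for K = 1..k_max (default 51) the
setting cases are scored from the training cases and the smallest K
maximizing the setting AUC is kept, separately for every variant and
scenario cell. k_max = 51 is a pragmatic scan bound (~13% of a 379-case
training set); tuned values in practice land well below it. Ties at the
K-th neighbor are broken by ascending case index (stable sort), making
predictions bit-reproducible.

## Degenerate inputs and numerics

* Constant or collinear attribute columns are dropped with a warning before
  fitting (noise blocks at small n can produce them).
* **Quasi-complete separation** (the MLE diverges; detected as Newton
  non-convergence with a coefficient beyond ±15, or a singular information
  matrix) raises an error by default. An optional weak ridge
  (λ = 1e-4 on slopes only, never the intercept, with step-halving Newton)
  is available via `ridge=True` / `ProtocolConfig(ridge_fallback=True)`;
  rare attributes (a few % prevalence) can separate a ~380-case training
  third for some random splits, and the acceptance script enables the
  fallback so every protocol cell remains fittable. If backward selection
  starts from an unfittable full model, the worst-diverging columns are
  greedily dropped first (logged) and selection proceeds from the largest
  fittable subset.
* Fitted probabilities are clamped to [1e-12, 1−1e-12] before residuals.
* Fusion scores are clamped to [0, 1]; renormalized weights can overshoot
  1 by one ulp when every neighbor label is 1.
* Similarity reductions run along the contiguous attribute axis with
  numpy's pairwise summation, so matrix and scalar paths agree bit-for-bit
  and the implementation can be checked for exact equality against a naive
  loop-based reimplementation (the test suite does this for all five
  variants on 50 random case bases).

## Evaluation protocol

The cohort is split into train / setting / evaluation thirds by simple
random sampling (unstratified by default — an explicit choice, with a
stratified option — and largest-remainder rounding so sizes are
deterministic: 1137 → 379/379/379). A per-attribute Pearson chi-squared
homogeneity check (df = parts − 1) is provided to confirm the parts are
comparable; constant attributes report statistic 0 / p 1 and are flagged
degenerate.

AUC uses the Mann–Whitney midrank form: P(score⁺ > score⁻) + ½P(tie).
`bootstrap_auc` draws B with-replacement resamples of the evaluation pairs
(B defaults to 500), reports the point AUC, the mean replicate AUC, and the
empirical 2.5/97.5 percentiles of the replicates as the 95% interval
(percentile method, no bias correction). Single-class resamples are redrawn
and counted; at ~23% prevalence and n ≈ 379 this is essentially never
triggered.

`run_protocol` evaluates all five variants over the 2 × 2 grid
{clean, +noise} × {all attributes, selected attributes}. Noise attributes
are appended **before** splitting and both scenarios reuse the same split
seed, so the clean/noisy comparison is paired on identical case rows, which
reduces the Monte-Carlo variance of the degradation contrast. Cell failures
(e.g. separation without the ridge fallback) are recorded per cell rather
than aborting the grid.

## Synthetic cohort

The generator emulates the structure of the original (non-public) registry
cohort: n = 1137 complete cases, 19 mutually independent Bernoulli
attributes of heterogeneous prevalence, and a label drawn from a logistic
model. The default preset uses one dominant coefficient (an age indicator,
β = 2.0), seven moderate clinical/care coefficients (|β| = 0.45–0.6) and
eleven null attributes, chosen so the fitted Wald-weight profile is
qualitatively "one dominant attribute plus several moderate ones" (the
dominant share lands around 55–65% at n = 1137). The intercept is calibrated
by 1-D root finding on the exact distribution of the linear predictor
(convolution over the ≤ 20 nonzero-coefficient attributes; Monte-Carlo with
2·10⁵ draws beyond that) so the marginal outcome prevalence hits the 23%
target within 1e-3.

Noise attributes are i.i.d. Bernoulli(0.5), independent of the label and of
each other — the distribution of the original study's "randomly defined"
factors is unstated, so a fair coin is the stand-in. An optional
Gaussian-copula correlation knob exists for the informative block but is off
by default: the real attributes are certainly correlated (age with
comorbidities, etc.), and this independence is the main respect in which
passing tests do not certify behaviour on real registry data. Other gaps:
no missingness process is simulated (the generator emits complete cases),
prevalences are stationary, and the true outcome model is exactly logistic —
so LR is the correctly specified benchmark here, which if anything
*understates* the hybrid's relative advantage under misspecification.

## Problem sizes used in checks

The test suite and acceptance script run at: parameter recovery n = 20 000;
robustness replication over 20 cohorts of n = 1137 with 50 noise attributes
and B = 100; the acceptance script uses 5 replicate cohorts with B = 200.
These sizes give stable Monte-Carlo contrasts (the degradation ordering is
reproduced with large margin) while keeping a full run in the minutes range
on a single core.

## Known limitations

* Attribute values must arrive binary; dichotomization of raw measurements
  is out of scope.
* Wald-based weights inherit the Wald test's weaknesses (Hauck–Donner
  effect near separation); the ridge fallback mitigates but does not remove
  this.
* The bootstrap resamples scores, not the whole learning pipeline: the
  interval reflects evaluation-set variability only, not split or fitting
  variability.
* No case-base maintenance (revise/retain steps of the CBR cycle) and no
  approximate-neighbor indexing; retrieval is exact and O(n·m) per query.
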