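# Methods

## Task and model family

The prediction target is binary: whether a patient returns to the ICU
within 30 days of discharge from an index ICU stay (boundary inclusive: a
readmission at exactly 30.0 days counts). Inputs per stay are a fixed
static covariate vector and two event streams — diagnosis/procedure codes
with elapsed times in days before the index ICU discharge, and
medication/vital-sign codes with elapsed times in hours. Codes of the index
admission are assigned elapsed time zero (the simplifying assumption that
discharge coding is available at discharge time).

All architectures end in a logistic output layer over
`[static, score_dxproc, score_medvit]`. Reducing each stream to a single
scalar score before the output layer is what makes the models
interpretable: the final-layer weights act as log-odds coefficients, and
single codes can be pushed through the score head to obtain per-code risk
scores. The two score weights are initialised at +1 (all other final-layer
weights at 0). This serves two purposes: it fixes the sign convention that
a higher code score means higher risk — the score scale is otherwise only
identified up to a sign flip absorbed by the output layer — and it lets
gradients reach the encoders from the first optimisation step. Zero
initialisation of the remaining output weights avoids saturated initial
logits, since numeric covariates (age in years, lengths of stay in days)
are deliberately passed through unstandardised to keep the odds-ratio
units interpretable.

## Time handling

Three mechanisms make embeddings time-aware: concatenating the raw elapsed
time as an extra coordinate; evolving the stored time-zero embedding by a
learned ODE (`dy/ds = f_θ(y)`, `f_θ` an MLP with three hidden layers of
the embedding width, tanh hidden activations, linear output), integrated by
the explicit Euler method with a fixed step count per solve (default 10;
fixed counts keep batched solves rectangular); or pretraining MCE
embeddings whose attention weights depend on bucketed time differences, so
each code's temporal scope is learned with its embedding.

Recurrent integration uses bi-directional GRUs with memory width equal to
the embedding width. Time gaps between consecutive events enter either as
an extra input coordinate, as exponential memory decay
`h ← h ⊙ exp(−softplus(w) Δt)` applied before each update, or as ODE
evolution of the memory state across the gap. Gaps are recomputed per
direction (the backward pass reads most-recent-first); whether the two
directions should share gaps is not a settled convention — per-direction
was chosen for symmetry. Events with equal timestamps are ordered by code
index for determinism; attention pooling itself is permutation-invariant
for simultaneous events, which the suite verifies to 1e-6.

Numerical rescaling: all times entering ODE blocks or decay/gap terms are
divided by a per-stream constant (365 for the day-scale stream, 24 for the
hour-scale stream). Euler steps over raw multi-year horizons would
otherwise be far outside the stable region early in training. The ODE
derivative MLPs additionally start with a zero output layer (`f ≡ 0`, the
identity flow) for the same reason. The elapsed time concatenated to
embeddings in `Attention(concat time)` is kept raw, per the model's
definition.

Dot-product attention is scaled by `√d` (numerically safer at widths around
10–12; switchable). The key projection is square, leaving the attended
width unchanged; pooled contexts are weighted averages of the inputs
themselves.

### MCE pretraining

The continuous-bag-of-words objective predicts each code from the others in
its sequence, with a learned attention scalar per (code, integer
time-difference bucket clipped at ±365 units) weighting the context.
Pretraining uses the training split only (using all data is possible but
would leak the test split's co-occurrence statistics into frozen features).
The returned matrix is the **average of the input- and output-side
matrices**: under CBOW-style objectives a consistently co-occurring pair
aligns the input vector of one with the output vector of the other, so the
input matrix alone anti-correlates exactly the pairs that should be
similar; the averaged matrix carries the co-occurrence geometry (the usual
word2vec reporting convention). Matrices stay frozen during supervised
training (a fine-tune switch exists).

## Training

Maximum-likelihood training minimises class-weighted log loss with Adam
(defaults: batch 128, learning rate 0.001, 80 epochs, no early stopping;
validation average precision is logged each epoch but not acted on).
Positive stays are weighted `N_neg/N_pos` from the training labels; on
balanced data the weighting is a no-op. Dropout (default 50%) applies after
embedding, recurrent and attention layers. The train/validation sub-split
within the pooled 90% is patient-level and seed-controlled. All randomness
flows through `numpy.random.Generator` objects derived from explicit seeds;
on a single CPU thread runs are bit-reproducible.

## Bayesian interpretation

Bayes by Backprop learns a mean-field Gaussian posterior `(μ, ρ)` per
weight, `σ = log(1+e^ρ)`, with one reparameterised weight draw per
minibatch step and the per-batch objective
`(log q(w) − log p(w))/n_batches + weighted NLL(batch|w)`, so the
complexity term sums to one KL per epoch. The prior is the scale mixture
`π N(0,σ₁²) + (1−π) N(0,σ₂²)` with π = 0.5, σ₁ = 1, σ₂ = e⁻⁶, evaluated
with a stable log-sum-exp. Local reparameterisation is not used — plain
per-weight sampling, as in the original algorithm. Training runs on the
entire data set and stops when the epoch loss has not improved for 10
consecutive epochs. Dropout is off during variational training (weight
noise already regularises).

Odds ratios are posterior means of `exp(w)` for the final-layer weights
(medians reported alongside, since the mean of a log-normal is not its
median); 95% credible intervals are 2.5/97.5 percentiles over sampled
weights (default 10,000 draws). Per-code scores are computed by scoring
each code as a one-event stay at elapsed time zero under sampled weights —
with one element the attention weight is exactly 1, so this is the head
applied to the embedding row.

## Evaluation

Reported metrics: average precision (step-wise sum over descending-score
thresholds), AUROC (rank statistic with tie correction), F1 maximised over
all thresholds, and sensitivity/specificity at the operating point
maximising Youden's J (ties broken toward higher sensitivity; with
completely uninformative scores this convention returns (1.0, 0.0)).
Point metrics come from scikit-learn; the test suite checks all four
against independent brute-force enumeration to 1e-10. Confidence intervals
are percentile bootstrap over 100 resamples drawn at the *patient* level —
a resampled patient contributes all stays, with multiplicity — and all five
metrics share each evaluation's replicates. Single-class replicates are
redrawn deterministically.

## Synthetic cohorts

The generator produces labelled cohorts with the statistical structure the
architectures are designed to exploit, with known ground truth:

* **risk model**: logit = `b₀ + x·β_static + Σ_events β_c exp(−λ_c t)`;
  labels are Bernoulli draws, so the generative risk is the Bayes-optimal
  score and upper-bounds any fitted model's discrimination.
* **time-decay heterogeneity**: 30% of codes are chronic (λ = 0); the rest
  decay at log-uniform rates (per day in roughly [0.01, 1] for dx/proc,
  per hour in [0.002, 0.1] for med/vit).
* **two time scales**: dx/proc elapsed times mix a point mass at zero
  (index-admission codes, probability 0.4) with an exponential tail (scale
  180 days, horizon 5 years); med/vit times are uniform over the stay
  duration.
* **irregular sampling**: negative-binomial sequence lengths (mean 8,
  dispersion 3 for dx/proc; mean 10, dispersion 4 for med/vit).
* **rare categories**: Zipf-like marginal code usage.
* **comorbidity structure**: codes belong to latent condition clusters
  (8 per stream); each patient activates two clusters and draws 70% of
  codes from them, and each code's effect is a cluster-shared component
  plus an idiosyncratic part. Real EMR codes co-occur within conditions
  and share risk; without this structure frozen co-occurrence embeddings
  (MCE) would carry no risk-relevant geometry at all.
* **class imbalance**: the intercept is calibrated by bisection on a
  simulated cohort so prevalence matches the 12% target (≈ the observed
  post-ICU readmission rate), verified at n = 20,000 within ±0.02.
* **statics**: the covariate list and reference groups mirror the schema
  of the MIMIC extraction stage (gender, age, ethnicity, insurance,
  marital status, admission location, elective surgery, ICU and pre-ICU
  lengths of stay, recent admissions), as Bernoulli/categorical/log-normal
  draws with fixed clinically-plausible effect directions.

What the generator does **not** emulate: real ICD-9 hierarchy and coding
practice, informative missingness, care-protocol correlations between
vitals and medications, non-stationary risk over calendar time, and
within-patient outcome correlation beyond shared covariates. Passing tests
therefore demonstrate that the implementations recover structure they are
designed for — not clinical-grade performance on real EMR data.

## Problem sizes in the test suite

The suite exercises the full pipeline at sizes chosen to make the checks
sharp but cheap, as the package's own test design: the architecture sweep
fits all 14 models on a cohort of 3,500 patients (25% held out) with
reduced epoch budgets per family (60 for attention-only models, 12 for
recurrent ones, Euler step count 3, dropout 0.2) — on this strongly
separable cohort (oracle AUROC ≥ 0.85, static effects scaled ×3 so even
the static-only baseline is competitive) every architecture must reach
AUROC ≥ 0.70 and every deep model must beat the logistic baseline.
Bayesian parameter recovery runs at 10,000 patients: planted static
effects of |logit effect| ≥ 0.3 must be recovered in sign, and
posterior-mean per-code scores must rank the planted code effects with
Spearman ≥ 0.8 in both streams. Interval calibration is checked on a
one-weight logistic toy model over 50 simulation replicates (≥ 90%
coverage of the generating coefficient).

## MIMIC-III extraction

The optional extraction stage turns raw MIMIC-III v1.4 CSVs into the same
schema. Documented choices: labels are computed on *all* ICU stays before
exclusions are applied (a readmission still counts as an outcome even if
the readmitting stay is itself excluded); any later ICUSTAY row counts as
a readmission candidate, including same-hospitalisation transfers; ages
shifted above 89 are capped at 90; the seven OASIS vitals are mapped from
a documented CHARTEVENTS/OUTPUTEVENTS item-id table (MetaVision and
CareVue ids — the source tables do not themselves name the items); urine
output is aggregated per calendar day before binning; out-of-physiological-
range measurements are dropped with a logged warning. OASIS cut-points are
hard-coded from the published categorisation; consecutive identical
vital-bin codes keep only the latest observation. The number of ICU
admissions in the prior year is computed on date-shifted timestamps and is
therefore only internally consistent, not calendar-accurate.

## Known limitations

The autodiff engine is dense-float64 and single-threaded; it is sized for
embedding widths ≈ 10–16 and cohort sizes ≈ 10⁴–10⁵ events, not for
GPU-scale workloads. Multi-head or key/value-separated attention, LSTM
cells, Bayesian ensembles, and within-patient clustering adjustments of
the risk model itself are out of scope. Bootstrap CIs are percentile-based;
credible intervals assume the mean-field family. Parameter recovery at
small cohort sizes is shrunk toward zero by the sparsity prior — sign
recovery for moderate effects needs cohorts in the 10⁴-patient range.
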