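# icurisk

Time-aware neural architectures for predicting **readmission to the ICU
within 30 days of discharge** from irregularly-timestamped electronic
medical record (EMR) codes, with a Bayesian attention model for describing
patients at risk.

## The problem

A patient's EMR is a set of static covariates (demographics, admission
details, lengths of stay) plus timestamped codes on two very different time
scales: ICD-9 diagnosis/procedure codes accumulated over years of clinical
history (elapsed time in *days* before the index ICU discharge), and
medications and OASIS-binned vital signs recorded during the index ICU stay
(elapsed time in *hours*). Codes are sampled irregularly and their
predictive relevance decays at code-specific rates — a chronic-disease code
stays informative for years, a transient finding does not. Standard
recurrent or attention layers ignore this; the architectures implemented
here handle it explicitly.

Every model shares one structure: codes → time-aware embeddings → a scalar
score per stream (via bi-directional GRUs and/or dot-product attention) →
`sigmoid(w · [static, score_dxproc, score_medvit] + b)`, a logistic output
layer whose weights read like regression coefficients.

The 13 neural recipes factor along three axes:

* **embedding time-handling** — end-to-end matrix (optionally with elapsed
  time concatenated), neural-ODE dynamics `dy/ds = f_θ(y)` Euler-integrated
  from the stored time-zero embedding over the elapsed time, or pretrained
  medical-concept embeddings (MCE) with learned time-aware attention;
* **sequence integration** — none, or a bi-directional GRU whose memory
  state handles time gaps by input concatenation, exponential decay
  `h ← h ⊙ exp(−softplus(w) Δt)`, or ODE evolution;
* **pooling** — the final memory states, or scaled dot-product attention
  `αᵢ = softmax(q·(K hᵢ)/√d)`.

Embedding width follows the fourth-root rule `d = round(2·V^{1/4})` for a
vocabulary of `V` codes. A static-covariates + most-recent-vitals logistic
regression serves as the baseline (14 models in total).

For interpretation, the `Attention(concat time)` model is trained with
**Bayes by Backprop**: a mean-field Gaussian posterior over every weight
with a scale-mixture prior (π = 0.5, σ₁ = 1, σ₂ = e⁻⁶), giving odds ratios
for static covariates and ranked per-code risk scores, each with 95%
credible intervals from posterior sampling.

All neural components run on a small reverse-mode automatic-differentiation
engine over NumPy arrays included in the package (`icurisk.autodiff`), so
the library is pure scientific-Python with no deep-learning framework
dependency.

## Worked example

```python
from icurisk import (GeneratorConfig, ReadmissionRiskModel, ArchSpec,
                     TrainConfig, simulate_cohort)

cohort, truth = simulate_cohort(GeneratorConfig(n_patients=2000, seed=42))
spec = ArchSpec(name="ODE+RNN", dropout=0.2, ode_steps=3, seed=0)
results = ReadmissionRiskModel(cohort, spec,
                               TrainConfig(epochs=12, learning_rate=0.005,
                                           seed=0)).fit()
print(results.summary())
print(results.evaluate(n_boot=100, seed=0).summary("ODE+RNN"))
```

prints

```
Readmission risk model
======================================================
architecture:     ODE+RNN
parameters:       2228
epochs trained:   12
final train loss: 0.4842
final valid AP:   0.4268
                       AvgPrec                 AUROC                    F1                  Sens                  Spec
ODE+RNN    0.558 [0.391,0.708]   0.821 [0.745,0.901]   0.569 [0.400,0.715]   0.732 [0.515,0.947]   0.822 [0.604,0.974]
```

The cohort here is synthetic: 2,586 stays with 11.8% positive labels drawn
from a generative model with known static effects and per-code
time-decaying effects. The evaluation row gives each metric's mean and 95%
CI over 100 patient-level bootstrap resamples of the held-out test split —
resampling patients (with all their stays) rather than stays, so
within-patient clustering is respected. F1 is maximised over thresholds;
sensitivity/specificity are reported at the Youden-optimal operating point.

The Bayesian side:

```python
from icurisk.bayes import BayesianAttentionModel
bayes = BayesianAttentionModel(cohort).fit(
    config=TrainConfig(epochs=1, learning_rate=0.005, seed=0),
    seed=0, max_epochs=60)
print(bayes.summary(n_samples=2000, seed=0))
```

prints, among the static covariates (posterior-mean odds ratio with 95%
credible interval; `*` marks intervals excluding 1),

```
  n_recent_admissions           1.442 [1.354, 1.535]*
  elective_surgery              0.485 [0.429, 0.544]*
  insurance_private             0.829 [0.787, 0.871]*
  score_dxproc                  1.848 [1.825, 1.872]*
  score_medvit                  3.344 [3.194, 3.497]*
```

e.g. each additional ICU admission in the preceding year multiplies the
odds of 30-day readmission by ≈1.44, while elective-surgery admissions have
roughly half the odds. `bayes.code_ranking("dx_proc")` ranks individual
codes by their posterior-mean risk score with credible intervals. Recovery
of planted effects sharpens with cohort size; the acceptance suite checks
sign recovery and rank correlation at n = 10,000 patients.

## Command line

```bash
icurisk simulate --n-patients 2000 --seed 1 --out cohort/
icurisk extract  --mimic-dir /path/to/mimic-iii --out cohort/   # optional
icurisk train    --cohort cohort/ --arch "ODE+RNN" --checkpoint model.npz
icurisk evaluate --cohort cohort/ --checkpoint model.npz --out report.json
icurisk interpret --cohort cohort/ --out interpretation/
```

`extract` implements the full MIMIC-III v1.4 cohort pipeline (exclusions,
30-day labelling, OASIS vital binning, rare-code relabelling, patient-level
splitting); MIMIC-III is credentialed-access and is **not** required for
anything else — the synthetic generator emits the identical schema.

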