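# Methods

This note records the modeling assumptions, defaults and design choices
behind `hncprog`, in the spirit of a model-description appendix. Nothing
here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Synthetic cohort generator

**What it emulates.** The generator reproduces the *tabular* structure of
a single-institution head-and-neck radiotherapy cohort: demographic (age,
sex), clinical (T/N/overall stage, disease site, ECOG performance status,
HPV status with an explicit "Not tested" level), treatment (radiation
dose in Gy, systemic-therapy flag) covariates, log-normal primary tumor
volume (cc), and right-censored overall-survival outcomes with a
diagnosis-date ordering used for the train/test split.

**Outcome model.** Survival times are drawn from a discrete monthly
hazard

    h_k(x) = min(baseline_hazard[k] · exp(β·x), 1),

where x is the encoded covariate vector (continuous variables
standardized by fixed anchors stored in the config, categoricals one-hot)
and β the ground-truth log-hazard coefficients. Beyond the hazard grid
(default 120 months) the last month's hazard repeats, so every patient
has a finite death time and a zero censoring rate yields an all-event
cohort. The continuous time is placed uniformly within the death month.

**Defaults.** Covariate mixes are chosen to resemble a definitive-
radiotherapy HNC population (76% male, 50% oropharynx, 50% stage IV, 30%
HPV untested, dose ≈ 66 ± 6 Gy, median tumor volume ≈ 20 cc). Coefficient
signs follow established prognostic factors: stage, age, performance
status and log-volume harmful; HPV positivity, dose and systemic therapy
protective. The constant baseline hazard of 0.004/month puts the marginal
2-year mortality near 0.2 — between the benchmark's reported test-set
prevalence (0.14) and its training period — and the default cohort size
(2,552; split 1,802/750 at `train_fraction = 0.706`) mirrors the
benchmark design. All values are configurable per variable.

**Censoring.** A `censoring_rate` fraction of patients (default 0.55)
receive an administrative censoring time uniform on [24, 84] months; a
patient is censored only if that time precedes their death time, so the
*realized* censored fraction is somewhat lower (~30% under defaults).
Drawing censor times at ≥ 24 months enforces by construction the cohort
inclusion rule — censored patients have at least two years of follow-up —
which is what makes 2-year binary labels unambiguous and lets the binary
metrics go uncorrected for censoring. The uniform administrative scheme
is a stand-in: the real cohort's censoring distribution is not public,
and none of the shipped analyses are sensitive to its shape beyond the
24-month floor.

**Boundary convention.** A death at exactly 24.0 months counts as a
2-year event (inclusive horizon); this resolves a measure-zero ambiguity
and matches the time-grid convention below.

**Synthetic feature block.** Engineered-imaging ("radiomics") features
are emulated as `volume_coupling · z + noise_sd · ε` with z the
standardized log tumor volume — capturing the well-documented volume
dependence of engineered radiomic signatures, which is exactly the
property the volume-dependence analysis probes. It does *not* emulate
feature-feature correlation structure, image noise, or any genuinely
volume-independent imaging signal, so a synthetic "radiomics" model can
never beat volume itself here; conclusions about real image features do
not follow.

**Randomness.** Each generator run spawns four independent streams
(covariates, survival, censoring, diagnosis order) from the single config
seed, so any stage can be reproduced in isolation. The pipeline derives
all of its seeds (cohort, feature block, per-model, evaluation) from one
master seed via `numpy.random.SeedSequence`.

**What passing tests show.** Because the generator satisfies the exact
discrete-time proportional-hazards form that a linear MTLR can represent,
parameter-recovery tests certify the estimation machinery, not real-world
performance; the realized metric values on synthetic cohorts are not
comparable to published values from the real cohort.

## Encoding

Full one-hot (no reference level dropped — every downstream model is
regularized, so the collinearity is benign) with an explicit missing
level per categorical variable ("Not tested" for HPV, "Missing"
otherwise); unseen levels at transform time map to the missing column
rather than widening the matrix. Continuous variables are standardized by
train-set statistics; volume enters as standardized log(volume). The
fitted schema is serialized to JSON and applied frozen to any evaluation
cohort, guaranteeing identical columns in identical order.

## MTLR

Time grid: 24 monthly intervals, boundaries at 1..24 months; interval k
covers (τ_{k−1}, τ_k] (right-inclusive, matching the binary-label
convention). A censored time inside interval k is treated as surviving
interval k (death strictly after k) — conservative and immaterial before
month 24 given the inclusion rule. Times beyond the grid (censored or
dead) are consistent only with the survive-all sequence.

Likelihood and gradients are computed in vectorized log-space (reverse
cumulative `logaddexp` for the censored tail sums); analytic gradients
are verified against central finite differences at 1e-5 relative
tolerance in the suite, and sequence probabilities/likelihood values
against explicit enumeration of all monotone sequences for K ≤ 6.

Optimization: the linear variant is concave and is maximized by
full-batch L-BFGS from zero with the objective scaled per-observation
(`gtol 1e-5`, `ftol 1e-10`, up to 2,000 iterations); repeated fits from
random starts agree in objective value. The deep variant (one ELU hidden
layer) is non-convex: He-initialized, seeded minibatch Adam (lr 1e-3,
batch 128, up to 300 epochs) with early stopping (patience 20) on a 10%
held-out split and restoration of the best parameters; the seed is
recorded in the results object.

Regularization defaults (λ_smooth = 10, λ_ridge = 1, hidden width 16)
were fixed once by 5-fold cross-validated grid search on the default
simulated cohort's training split — the same tuning protocol the
baselines use — over hidden ∈ {none, 16, 32, 64}, λ_smooth ∈ {1, 10,
100}, λ_ridge ∈ {0.01, 0.1, 1}; validation AUROC was flat to ~0.005
across the grid, so the choice is not delicate.

Risk score: the discrete expected dead-time Σ_k (1 − S(τ_k)). The
benchmark never defined the winning model's scalar risk; any strictly
monotone functional of the curve would do, and this one is strictly
increasing in every interval's death probability and coincides in
ranking with the 2-year event probability whenever curves do not cross
(asserted on constructed non-crossing cases in the suite).

Model parameters (grid, weights, biases, encoder, seed) serialize to
JSON; a reloaded model predicts bit-identically, which is what the
external-validation hand-off relies on.

## Baselines

- **Logistic** (binary endpoint): l2-penalized maximum likelihood via
  scikit-learn (`C = 1/l2_strength`, lbfgs, tol 1e-10); cross-checked in
  the suite against an independent scipy minimization of the same
  penalized objective.
- **Cox** (survival endpoint): lifelines `CoxPHFitter` with Breslow tie
  handling (ties are measure-zero in the simulated times anyway);
  zero-variance columns (never-observed missing levels) are dropped for
  the Newton solve and restored with coefficient 0. A hand-written
  Breslow partial log-likelihood serves as the test oracle. For the
  binary task the Cox risk is mapped to a probability by a one-
  dimensional logistic (Platt) calibration fitted on training data.
- **Volume-only**: the same logistic/Cox machinery on standardized
  log-volume alone.
- **mRMR**: greedy difference criterion — mutual information with the
  label minus mean mutual information with already-selected features —
  on equal-frequency 8-bin discretizations. The variant (difference vs
  quotient), the MI estimator and the binning are unspecified in the
  benchmark description; the choice is isolated behind
  `mrmr_select(..., redundancy_weight=...)`, and with the redundancy
  term disabled it reduces exactly to relevance ranking (tested).
- **Tuning**: grid search over stratified 5-fold CV maximizing mean
  validation AUROC, folds seeded, ties broken toward stronger
  regularization / fewer features.

## Evaluation and inference

- AUROC is the normalized Mann–Whitney rank sum (midranks for ties); AP
  is the precision-recall step sum Σ (R_n − R_{n−1}) P_n with tied
  scores grouped at one threshold. Both are implemented directly in
  numpy for speed inside resampling loops and are verified against both
  exhaustive enumeration oracles and the scikit-learn reference
  implementations. Note AP's expectation under random scores exceeds the
  prevalence by O(1/n_pos); at n = 750, prevalence 0.14 the mean is
  ≈ 0.147, which is why "random AP ≈ prevalence" holds only
  asymptotically.
- C-index is Harrell's convention via lifelines: comparable pairs are
  (t_i < t_j, event_i = 1); risk ties earn ½; equal-time pairs follow
  lifelines' standard handling (a death tied with a censoring is
  comparable; two tied deaths are scored by prediction agreement). Zero
  comparable pairs raise an undefined-metric error.
- No IPCW/censoring correction is applied to binary metrics — the
  inclusion rule makes 2-year labels exact, deliberately mirroring the
  benchmark's protocol.
- Confidence intervals: percentile bootstrap with resampling stratified
  on the outcome (binary label, or event indicator for the C-index),
  default 10,000 replicates for standalone use; coverage for AUROC is
  checked empirically in the suite (500 replications at 1,000
  replicates, nominal 95%, accepted band 92–98%).
- Permutation tests permute outcomes jointly, use add-one smoothing
  (p ≥ 1/(n_perm+1)), and their type-I error is checked at α = 0.05 over
  500 null simulations.
- Model-vs-best comparison: both models are evaluated on shared
  stratified bootstrap replicates; the mean per-replicate AUROC
  difference divided by the replicate SD (the bootstrap standard error
  of the difference) is referred to a t distribution with B−1 degrees of
  freedom, one-sided. Identical score vectors return p = 1 by
  convention. (A one-sample t test on the replicates themselves would
  shrink the standard error by √B and flag arbitrarily small
  differences.) Benjamini–Hochberg at q = 0.05 corrects across models;
  the same step-up routine (statsmodels) is used for the cohort-shift
  tests and is verified against the literal step-up definition.
- χ² cohort-shift tests use plain Σ(O−E)²/E (no Yates correction, so
  hand arithmetic matches exactly); continuous variables are
  quartile-binned on the pooled sample; expected counts below 5 warn
  rather than switching to an exact test.
- Risk stratification: groups split at event-probability ≥ 0.5;
  Kaplan–Meier per group, hazard ratio from a univariate Cox fit on the
  group indicator, log-rank p (all lifelines).

## Pipeline

`run_challenge` trains the roster only on the date-ordered training
split; test outcomes sit behind a `HeldOutOutcomes` guard that refuses to
reveal them until every model's predictions are frozen, enforcing the
challenge's blinding structurally (and tested by attempting a violating
call). Ranking sorts by AUROC with AP as tie-break; every model is
compared one-sidedly to the best at 5% FDR. Model failures are non-fatal:
the pipeline records them and ranks whatever completed.

External validation regenerates cohorts under named covariate shifts
(ground-truth coefficients and standardization anchors untouched — pure
covariate shift), applies the frozen schema and frozen models, and runs
the per-variable χ²/FDR shift analysis against the internal test set.
Three qualitative presets ship — a site-mix shift, a stage-mix
(prevalence) shift and an HPV-negative-heavy shift; their magnitudes are
illustrative, not estimates of any real external cohort.

The pipeline's default bootstrap size is 1,000 replicates (the standalone
metric-CI default remains 10,000): across seven models and three metrics
the CI endpoints move by well under the interval width while the default
run stays interactive. Reports are written as CSV + JSON plus a rendered
text summary; re-rendering the saved JSON reproduces the summary
byte-for-byte, and a config digest and all derived seeds are embedded.

## Known limitations

- The generator's hazard is exactly proportional and time-constant, so
  MTLR's signature advantage — learning time-varying effects — is not
  exercised by the default cohort; adding interval-varying β is the
  natural extension.
- The synthetic feature block cannot produce volume-independent imaging
  signal, so image-only models are structurally capped below volume-using
  models here.
- The deep variant's likelihood is non-convex; determinism is guaranteed
  per seed, global optimality is not.
- `compare_models`' bootstrap-t construction treats replicate differences
  as draws from the sampling distribution of the AUROC difference; it is
  a pragmatic convention, not an exact test.
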