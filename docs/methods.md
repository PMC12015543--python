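# Methods

## Problem and pipeline

`alngraph` implements a comparative evaluation of three graph neural
network families — GCN, GAT and GIN — for predicting axillary lymph
node metastasis (ALNM) in early-stage breast cancer from routine
clinicopathologic variables and nine binary axillary-ultrasound
findings ("Terms 1–9"). Patients are not treated as independent rows:
each cohort is turned into a *patient-similarity population graph*
whose nodes are patients and whose edges connect patients with
near-identical standardized feature vectors, and the classifiers
operate transductively on that graph.

The pipeline stages are:

1. **Cohort.** A per-patient table (age in years, ultrasound tumour
   size in mm, ordinal tumour location 1–4, histologic type 1–3,
   BI-RADS category 1–4 coding 4A/4B/4C/5, ER/PR/Ki-67 percentages,
   binary HER2, Terms 1–9, and the binary ALN label), either loaded
   from CSV or produced by the synthetic generator below.
2. **Split.** Random 4:1 train/test partition, stratified by label.
   The rounding rule is floor(n_class · ratio) per class into training;
   on a 584-patient cohort with 247 metastatic this yields exactly
   466/118.
3. **Univariate screen.** Each feature is regressed alone
   (intercept + slope) against the label by IRLS maximum likelihood.
   Wald standard errors come from the inverse observed information;
   95% CIs are exp(β ± 1.959964·SE); p-values are two-sided Wald.
   Degenerate fits (zero-variance predictor, an empty cell in a binary
   predictor's 2×2 table, or |β| > 15 — a quasi-separation guard) are
   reported as not-available rather than as spurious estimates.
4. **Graph construction.** The candidate factors are z-scored with a
   scaler fit on the training cohort only (population sd, denominator
   n). Pairwise cosine similarity between standardized rows is
   thresholded at τ = 0.95 (inclusive); `A[i,j] = 1` iff
   `S[i,j] ≥ τ`, no self-loops, isolated nodes permitted. Train and
   test graphs are built separately, with no train–test edges, so
   evaluation is inductive application of the trained weights to an
   unseen graph.
5. **Training.** Full-batch transductive training: each epoch is one
   forward/backward pass over the whole graph followed by a
   bias-corrected Adam update (lr 1e-4, β₁ 0.9, β₂ 0.999, 1000
   epochs, softmax cross-entropy against one-hot labels). An optional
   minibatch mode subsamples 32 labelled nodes per step for the loss
   while keeping the full-graph forward pass; full-batch is the
   default because a "batch" is not otherwise well defined for
   whole-graph message passing.
6. **Evaluation.** Confusion matrix at probability threshold 0.5 on
   the class-1 (metastasis) probability, with ties classified
   positive; SEN/SPEC/PPV/NPV/ACC/F1 with NaN for empty denominators;
   ROC with trapezoidal AUC (tie-simultaneous thresholds, hence equal
   to the Mann-Whitney rank statistic); class-stratified percentile
   bootstrap CI for the AUC (2000 resamples by default); PR curve with
   step-weighted average precision; and the phi coefficient (Pearson
   correlation of the 0/1 prediction vectors) for pairwise model
   agreement.

## Model cores

All three layer families are implemented densely in float64 with
hand-derived backward passes (cohort graphs have a few hundred nodes,
so sparse storage would buy nothing).

* **GCN**: `H' = act(D̃^{-1/2} (A+I) D̃^{-1/2} H W + b)`, final layer
  linear to 2 logits.
* **GAT** (single head): `z_i = W h_i`,
  `e_ij = LeakyReLU(aᵀ[z_i ‖ z_j])` over the closed neighbourhood,
  `α_ij = softmax_j(e_ij)`, `h'_i = act(Σ_j α_ij z_j)`; LeakyReLU
  slope 0.2.
* **GIN**: `h'_i = MLP((1+ε) h_i + Σ_{j∈N(i)} h_j)` with a two-affine
  ReLU MLP per layer and trainable ε initialised at 0, followed by a
  linear readout.

Self-connections live inside the layers (A+I for GCN, self-attention
for GAT, the (1+ε) term for GIN); the edge table itself has no
self-loops. Defaults are depth 2, hidden width 16, ReLU, no dropout —
standard small-data choices for these families, all configurable.
Weights are Glorot-uniform from a seeded generator; biases and ε start
at zero. Analytic gradients for every parameter of every architecture
are validated against central finite differences (step 1e-5, relative
tolerance 1e-5) in the test suite.

## Synthetic cohort generator

The generator emulates the published cohort's composition so the whole
pipeline is testable without the original patient data: ALNM
prevalence 0.423; age 50.46 ± 10.36 years truncated to [18, 100];
tumour size 19.06 ± 6.57 mm truncated to (0, 40] (the study excluded
masses over 3.5 cm); the printed category frequencies for location,
type and BI-RADS; the printed positivity rates for HER2 and Terms 1–9;
and the printed univariate log-odds effects as the planted
feature–outcome structure.

Mechanism: the label is drawn first, Bernoulli(prevalence); every
feature is then drawn conditionally on the label.

* **Binary and ordinal features** use an exactly-tilted conditional
  construction: class-conditional distributions Q0, Q1 with
  `Q1(c) ∝ Q0(c)·exp(effect·c)` whose mixture equals the target
  marginal *exactly* (the normalising constant is found by 1-D root
  finding). Consequently the population log odds-ratio of label given
  feature equals the configured effect exactly, and the marginal rates
  are exact — planted effects are recoverable by the univariate screen
  in closed loop, which the parameter-recovery tests exploit.
* **Continuous features** use class-shifted truncated normals with a
  common sd and shift `effect · sd²`, the shift that induces the
  configured logistic slope under a common-variance normal model
  (truncation perturbs this slightly; the configured effects are small
  enough that the perturbation is far below the screen's SE).

Two defaults deserve note. Term 8 had *zero* positives in the emulated
training cohort (its screen row is degenerate/NA); a zero base rate
would make the default generator degenerate, so the default is the
test-cohort rate 0.017 and the value is configurable. Term 8's effect
defaults to 0 because no coefficient was reported. The ER/PR/Ki-67
percentage distributions are only summarised as positive/negative
rates in the source; the generator uses truncated normals
(means 60/55/40, sds 30/30/25 on the 0–100 scale) as a plausible
shape — their near-zero configured effects make this choice
inconsequential downstream.

What the generator does **not** emulate: correlations *between*
features beyond those induced by the shared label (real ultrasound
findings co-occur), measurement error, missingness, site effects, or
any image-level information. Passing tests therefore demonstrate that
the pipeline's machinery is correct and that planted signal of the
published magnitude is learnable — not that the published real-data
AUCs are reproduced. Those require the original external dataset,
which the pipeline accepts in CSV mode.

## Candidate-factor selection

The screen selects features with Wald p < 0.05 by default. The
pipeline's reproduction default instead uses the fixed ten-factor
panel (tumour size, location, Terms 1–7 and 9) that the published
analysis carried forward — notably excluding BI-RADS despite its
nominally significant univariate p. Both behaviours are exposed
(`factor_mode="panel" | "screen"` or an explicit list); the package
takes no position on why the published set excludes BI-RADS. A
selected factor that is constant in the realised training cohort
(possible for rare terms at small n) is dropped before scaling, with a
log warning and a manifest record, since it carries no contrast.

## Numerical choices

* IRLS: convergence when the largest coefficient change < 1e-8, cap
  100 iterations; linear predictor clipped to ±30 inside the sigmoid;
  log-likelihood is non-decreasing across iterations (tested).
* Cosine similarity is symmetrised and clipped to [−1, 1]; rows of
  zero norm are an error naming the row.
* Ties at the similarity threshold are *included* (≥, as specified);
  ties in ROC thresholds are included simultaneously; prediction ties
  at probability 0.5 are classified positive. All three tie rules are
  documented because SEN/SPEC pairs depend on them.
* Softmax and cross-entropy are max-shifted for stability; the loss
  gradient is `(softmax − Y)/n`.
* A single global seed derives per-stage sub-seeds (cohort, split,
  per-architecture init, training, bootstrap) via `SeedSequence`, so
  stages can be re-run in isolation and two runs with the same
  configuration are byte-identical — verified end to end at full scale
  (584 patients, three architectures, 1000 epochs) in the test suite.

## Problem sizes

Default experiments use the emulated cohort scale throughout: 584
patients (466/118 after the 4:1 split), ten candidate factors,
τ = 0.95, 1000 epochs. Marginal-calibration tests draw 10k–20k
patients; parameter-recovery tests use n = 5000, matching the scale at
which the Wald CIs are informative. The bootstrap uses 2000 resamples
in the pipeline default and 1000 in the acceptance script.

## Known limitations

* Single-head attention only; no edge weights, multi-graph batching,
  or GPU path — out of scope for cohort-scale node classification.
* The AUC interval method in the source is unstated; the percentile
  bootstrap here makes no claim of matching it.
* Real-data performance figures are outside what synthetic cohorts can
  certify (see above); the end-to-end synthetic run reports its own
  AUCs as descriptive output only.
* The IRLS screen handles perfect separation by flagging, not by
  penalised (Firth) estimation; with the emulated effect sizes and
  n ≥ a few hundred this is only reached by genuinely degenerate
  predictors.
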