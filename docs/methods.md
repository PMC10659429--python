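# Methods

This note documents the models and procedures implemented in `fedomics`,
the assumptions behind them, and the design choices made where the design
was genuinely open. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## 1. The synthetic cohort generator

Real multi-omics Parkinson's cohorts are access-controlled, so the
generator is this package's own construction: it emulates the *structure*
of such data — block composition, sample sizes, confounding, an
out-of-distribution external cohort — not any particular dataset's values.

### Generative model

Truth (drawn once per seed, before any samples, so cohort-size changes
never reshuffle it): minor allele frequencies maf_j ~ U(maf_low, maf_high)
for `n_snp` variants; a random subset of `n_causal_snp` variants receives
liability effects β_g ~ N(0, beta_scale_genetic²); expression effects
β_e ~ N(0, beta_scale_expr²); per-gene confounder loadings w_k ~ N(0,1)
and disease-signature loadings d_k ~ N(0, expr_disease_loading²);
clinical effects β_c ~ N(0, beta_scale_clin²) with the smell-score
coefficient forced negative (a low score marks the disease).

Per sample:

* ancestry a ~ N(0,1);
* genotype dosage g_j ~ Binomial(2, p_j) with
  logit p_j = logit(maf_j) + confound_strength · a;
* PRS = standardized Σ_causal β_j g_j (an *idealized* polygenic score —
  the true causal effects stand in for external GWAS weights, which cannot
  be shipped);
* expression e_k = confound_strength · a · w_k + ℓ̃ · d_k + N(0,1), where
  ℓ̃ is the sample's standardized genetic liability contribution — the
  d_k term spreads a diffuse, redundant disease signature over the
  transcriptome, which is what makes expression data informative to a
  ridge-type linear model at p ≈ n;
* clinical features: age ~ N(61, 10²), sex ~ Bern(0.5), family history
  ~ Bern(0.15), smell score ~ N(25, 8²), one extra standard-normal
  covariate; their liability contributions use the standardized latents;
* liability L = g·β_g + e·β_e + x̃·β_c + N(0, noise_sd²); case ⇔
  L > threshold.

The threshold is the (1 − target prevalence) quantile of liability over a
fixed 4,000-draw calibration pool (also the source of the PRS and
liability standardization constants), making the feature definition
independent of the requested cohort size. Rejection sampling then fills
exactly `(n_cases, n_controls)`; exceeding 500 × cohort-size candidate
draws raises an explicit error (this is how a degenerate spec — zero
effects with zero noise — fails).

Linked cohorts share one truth; the external cohort multiplies every
liability coefficient by `shift_effect_scale` and offsets the stored
transcriptomic block by `shift_mean` *after* liability is computed — a
pure covariate/effect shift emulating post-treatment measurement
artifacts. Internal and external sampling streams are salted
independently, so equal seeds do not correlate the cohorts.

### Default parameters and their calibration

| parameter | default | why |
|---|---|---|
| n_snp / n_expr / n_clin | 71 / 596 / 5 (+1 PRS) | emulated feature-space composition |
| maf_low, maf_high | 0.05, 0.5 | common-variant regime (cases-MAF > 5% filter analogue) |
| n_causal_snp | min(20, n_snp) | sparse causal architecture |
| beta_scale_genetic | 0.8 | see below |
| beta_scale_expr | 0.02 | expression mostly nuisance + signature |
| expr_disease_loading | 0.5 | diffuse transcriptomic signature |
| beta_scale_clin | 0.6 | few strong clinical predictors |
| confound_strength | 0.5 | visible but removable substructure |
| noise_sd | 0.8 | unexplained liability |

The effect scales were fixed once, by Monte-Carlo before the test suite
was written, to put regularized logistic regression at a realistic,
non-saturated operating point (test AUC-PR ≈ 0.78–0.80 at 598 samples ×
673 features, prevalence 0.286). Two structural lessons from that
calibration are worth recording: (i) spreading liability variance over
hundreds of *independent* small expression effects caps any linear
classifier near chance-plus at this n/p — converged ridge logistic
regression plateaued near 0.58 AUC-PR — whereas a diffuse correlated
signature (the d_k term) is learnable, which mirrors how real disease
transcriptomics behaves; (ii) the PRS column, being a sufficient
statistic for the genetic contribution, absorbs the SNP-level signal in
any joint fit — which is why parameter-recovery checks fit the genetic
block alone (see §6).

### What the generator does *not* emulate

No linkage-disequilibrium structure, no Hardy–Weinberg filtering, no
RNA-seq count noise (expression is Gaussian post-normalization), no
longitudinal visits, no site-of-origin structure. Passing tests therefore
demonstrate correctness of the *pipeline machinery* and the qualitative
federation phenomena on a plausible data geometry — not performance claims
about any real cohort.

## 2. Preprocessing

Fitting happens on training data only; `transform` applies stored
parameters (PC loadings and centers, residual regression coefficients,
Z-parameters, the selected feature list) with no refit. Specifics:

* **Block PCs** — top-k right singular vectors of the centered block
  (k = 10 per block by default); k above the numerical rank
  (singular values ≤ s₀·1e-10) is an error.
* **Residualization** — least squares of every feature on
  (intercept + own-block PC scores); genetic features on genetic PCs,
  transcriptomic on transcriptomic PCs, PRS and clinical untouched.
  Rank-deficient covariate columns are zeroed with a warning.
* **Z-transform** — population-sd convention (divide by n), fixed and
  asserted at 1e-10; binary 0/1 columns pass through; constant training
  columns are flagged and skipped.
* **Selection** — Gini importance over an extremely-randomized-trees
  ensemble (512 trees, √p candidate features, one uniform-random
  threshold per candidate — scikit-learn's `ExtraTreesClassifier`, which
  is exactly this construction), then greedy pruning of any feature whose
  squared Pearson correlation with a kept higher-ranked feature exceeds
  0.36, then the top `keep` survivors. Off by default (`select=False`):
  the learner benchmarks operate on the full feature space, and turning
  selection on is a config choice.

## 3. Partitioning

* **K folds** — per class, quotas of ⌊n_c/K⌋ with the remainder assigned
  one-by-one to the folds with the smallest running totals (ties to the
  lowest index). This keeps per-class fold counts within ±1 *and* total
  fold sizes within ±1 (a plain per-class round-robin can make the two
  remainders collide on one fold: 171/427 at K=6 would give a
  101-sample fold).
* **uniform_stratified** — per-class shuffle, ⌊n_c/N⌋ per client, both
  class surpluses to the last client (a deterministic `surplus="last"`
  rule; `surplus="random"` is available). Consequence: non-last clients
  match the global case fraction exactly; the last client may deviate by
  up to N−1 samples per class.
* **uniform_random** — global shuffle, ⌊C/N⌋ each, surplus to last.
* **linear_random** — base c = ⌊C/(N(N+1)/2)⌋, client i gets i·c samples,
  surplus to last, so sizes increase strictly and sum to C; c = 0 is an
  explicit error.
* **Validation** — every generated partition is checked for disjointness,
  exact coverage, and ≥1 case and ≥1 control per silo (the minimum for a
  local learner to train). `validate_partition` reports rather than
  raises, so sweep drivers can skip infeasible configurations and log
  them; `split_clients` raises on a failed report.
* Client partitions are re-drawn per CV fold from fold-derived seeds
  (`repartition_per_fold=True`), so fold results are independent draws of
  the silo assignment; a flag restores a single fixed partition.

## 4. Learners and local training

All gradient learners (logistic regression, linear SGD, one-hidden-layer
MLP) share a flat-vector weights contract with a named block layout, so
averaging and the proximal term are uniform. Training is written
explicitly (not delegated to a library solver) because FedProx requires
exact warm-start and proximal-gradient semantics:

* **logreg** — full-batch gradient descent on mean log-loss +
  (l2/2)‖coef‖² (intercept unpenalized); default lr 1.0 on Z-scored
  features, 20 local epochs.
* **sgd_linear** — the same objective via single-sample SGD, per-epoch
  seeded shuffling, constant lr 0.05.
* **mlp** — one hidden layer (32 ReLU units), logistic output, Glorot
  uniform init, full-batch gradient descent, lr 0.05. The smallest
  architecture consistent with an "MLP classifier" at these sample sizes;
  every choice is config-overridable.
* **tree_ensemble** — `n_trees` CART trees on bootstrap resamples
  (scikit-learn `DecisionTreeClassifier`, max_depth 4, √p features per
  split), extracted into plain node arrays; routing and ensemble
  averaging are implemented here. The proximal term is undefined for
  trees and requesting it is a config error.

**Proximal step.** The FedProx objective F_k(w) + (μ/2)‖w − wᵗ‖² is
optimized with the data gradient taken explicitly and the proximal term
implicitly (backward Euler):

    w ← (w − lr·∇F_k(w) + lr·μ·wᵗ) / (1 + lr·μ)

This is identical to plain gradient descent at μ = 0, agrees with the
explicit step to O(lr·μ), and — unlike the explicit step, which diverges
once lr·μ > 2 — is unconditionally stable, so the μ → ∞ limit cleanly
pins w to the anchor. The intercept participates in the proximal norm and
in averaging (the aggregation rule draws no distinction between blocks);
the l2 penalty excludes it.

## 5. Federation

Synchronous, failure-free, in-process simulation. Each round: every
client warm-starts from the current global model (which is also the
FedProx anchor), local-fits, the server aggregates — unweighted
element-wise mean for gradient learners, even under size-skewed
partitions; tree pooling (client order, then local order) for ensembles —
and the global model is scored on the validation split. After R rounds
(default 5) the round maximizing the selection metric (default AUC-PR,
ties to the earlier round) supplies the final model; the final-round
model is also retained for equivalence checks. A sample-weighted
averaging option exists but is off by default. Per-phase wall-clock
seconds are logged for runtime accounting and never asserted — they are
hardware-bound.

Tree-ensemble federation is *federated bagging*: each round the clients
refit local bootstrap ensembles and the server pools the trees. This is a
documented stand-in — parameter averaging is undefined for trees, and no
canonical cross-silo aggregation for random-forest-style learners exists
to copy.

## 6. Evaluation protocol and numerical choices

* K = 6 stratified folds; per fold the held-out fold is the internal test
  set, the remaining folds are preprocessed (fit on them only) and split
  80:20 into training and validation; central learners fit on the
  training subset; federated learners fit on a partition of that same
  subset; the external cohort is transformed with the fold's
  preprocessing and evaluated whole.
* Threshold metrics are computed at 0.5 (configurable). Zero-denominator
  conventions: precision with no positive calls = 0, F_β with P = R = 0
  is 0, MCC with a degenerate confusion matrix = 0 (keeps sweep tables
  total). AUC-PR uses the average-precision formulation with tied scores
  entering as one threshold group. ROC-AUC is Mann–Whitney with ties at
  ½. Log-loss clips probabilities to [1e-15, 1−1e-15].
* Summary cells are mean ± *population* sd over the K fold values, and
  fold-level records are retained so every cell is recomputable.
* The seed-replicated findings use a lighter unit than full K-fold CV:
  per seed, one fresh default cohort, a stratified 75:25 train/test
  split, Z-scoring, then central logistic regression (R·E = 250 epochs,
  keeping the best of R epoch-checkpoints on the validation split —
  symmetric to the federated round selection, otherwise the comparison
  confounds early stopping with federation) against the federated
  variants on identical data. Twenty seeds give stable means at a few
  seconds per seed; full CV per seed would add nothing but fold-level
  averaging to a quantity that is already a cross-seed mean.
* Problem sizes in tests are deliberately modest (140–600-sample
  cohorts, reduced feature blocks for machinery tests, full 598 × 673
  geometry where the claim is about the study design); the acceptance
  script runs the full geometry.

## 7. Parameter recovery and selection checks

Two checks quantify whether the generator's ground truth is recoverable:

* **Sign recovery** — central logistic regression on the *genetic block*
  of a genetics-driven cohort (n = 600, effects only through β_g)
  recovers the signs of the 20 causal coefficients (median ≥ 90% over 10
  seeds). The genetic-block restriction is deliberate: in a joint fit the
  PRS column, a sufficient statistic for g·β_g, absorbs the SNP signal —
  a collinearity property of the design, not an estimation failure.
* **Selection retention** — extremely-randomized-trees selection with
  keep = 50 retains the detectable causal SNPs (median ≥ 12 of 20 over
  10 seeds). The ceiling is structural: with Gaussian effect sizes,
  roughly a quarter of "causal" coefficients are small enough
  (|β| < 0.35) to be statistically invisible at n = 600, so no selector
  can retain them above chance.

## 8. Known limitations

* The generator's Gaussian, block-structured data is easier than real
  multi-omics: no batch effects, missingness, platform noise or LD.
* Unweighted FedAvg is the only averaging rule exercised by default;
  weighted averaging exists but is untested against the findings.
* The federated tree rule (bagging union) is a stand-in; conclusions
  about tree learners under federation carry that caveat.
* Hyperparameters are fixed defaults (an optional grid is a config
  concern, not implemented as search); runtime numbers are recorded but
  hardware-dependent and never compared.
* Statistical significance testing of pairwise model differences is out
  of scope; fold-level records are retained so a paired test can be added
  on top.
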