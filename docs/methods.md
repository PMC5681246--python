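# Methods

## The model

A polygenic score for individual *i* is a weighted allele sum
`s_i = Σ_j x_ij w_j` over SNP dosages `x_ij`. Given marginal GWAS estimates
β̂ (per standardized allele), sample size N, SNP count M and trait
heritability h², the weights are posterior means under a Gaussian prior,
conditioning on LD:

* **Infinitesimal prior** (all SNPs causal, effect variance h²/M): per LD
  window, `w = (D + (M/(N h²)) I)⁻¹ β̂`, where D is the window's dosage
  correlation matrix. With D = I this is the scalar shrinkage
  `β̂ · N h² / (N h² + M)`.
* **Point-normal prior** (SNP causal with probability p, causal variance
  h²/(M p)): no closed form; a per-SNP Gibbs sampler iterates over windows,
  computing for each SNP the residual marginal effect
  `β̃_j = β̂_j − Σ_{k≠j} D_jk w_k`, the posterior inclusion probability from
  the two-component marginal likelihood, and a draw of the effect. The
  reported weight is the post-burn-in average of the Rao–Blackwellized
  conditional mean (inclusion probability × conditional shrinkage × β̃_j),
  which converges to the same posterior mean as averaging the draws but with
  lower Monte-Carlo variance. All random draws are pre-generated from a
  seeded generator, making the sampler bit-reproducible; a divergence guard
  aborts if any weight exceeds 100× the scale of the inputs.

Scores for every (GWAS, causal fraction) pair are standardized (mean 0, SD 1,
population convention) and residualized on genotype principal components to
remove population-stratification signal, exactly as one does before entering
them into phenotype regressions.

The **multi-polygenic score (MPS) model** is an elastic net over the per-GWAS
best score variants:

```
min_{β0, β} (1/2n) Σ_i (y_i − β0 − x_i'β)² + λ [ α‖β‖₁ + (1−α)/2 ‖β‖₂² ]
```

solved by cyclic coordinate descent with soft-thresholding
(`β_j ← S(ρ_j, λα)/(q_j + λ(1−α))`, `q_j = (1/n)x_j'x_j`), warm-started along
a log-spaced λ path. The objective is non-increasing every sweep; convergence
is declared when the largest coefficient change falls below 1e−7 (cap 10 000
sweeps). Because the design columns are standardized scores, fitted
coefficients are standardized coefficients and the L2 term gives the grouping
effect: exactly duplicated predictors receive equal coefficients.

## Cross-validation and model selection

Training uses k-fold cross-validation (k = 10) with `repeats` independent
random partitions. Per GWAS, simple regressions on the p ∈ {1, 0.1, 0.01}
score variants are compared by mean cross-validated R² and the best variant
is carried forward (ties to the sparsest prior). For the elastic net, (α, λ)
are tuned over α ∈ {0, 0.1, …, 1} × 100 log-spaced λ values (λ_min =
λ_max·10⁻³; the α = 0.001 surrogate defines λ_max on the ridge-only path).
The winning pair minimizes mean cross-validated squared error — the
"performance value / smallest mean squared error" criterion — with ties
broken to the largest λ. Mean cv-R² is computed and reported for the winner.
Squared error rather than the squared-correlation R² is used for *selection*
because the correlation metric is scale-free and therefore can never prefer
the empty model, even when no predictor carries signal.

R² is reported as the squared Pearson correlation between observed and
predicted values (the convention of the cross-validation framework this
design follows); the `1 − SS_res/SS_tot` variant is available via
`convention="ss"`. The correlation convention cannot distinguish a
sign-reversed predictor — a documented caveat, irrelevant once models are fit
by least squares.

## Evaluation

Individuals are split 60/40 (train/test) once, shared by all models.
The MPS-vs-best-single comparison on the test set uses a permutation test of
model exchangeability: each of B permutations independently swaps the two
models' predictions per individual with probability ½ and recomputes
ΔR²; the two-sided empirical p-value is `(r+1)/(B+1)` with r the count of
null |ΔR²| at least as extreme as observed. Observation-level swapping is
used because a model-level swap admits only two distinct statistics. The
per-individual swap scheme and the two-sided convention are both exposed as
arguments.

Decile stratification bins test individuals by predicted score (ties broken
by stable rank, so bin sizes differ by at most one) and reports per-bin mean
outcomes with normal 95% CIs (mean ± 1.96·SD/√n). The top-vs-bottom contrast
is summarized by Cohen's d (pooled-SD denominator; CI via
`SE = √((n₁+n₂)/(n₁n₂) + d²/(2(n₁+n₂)))`), U3 = Φ(d) (fraction of the top
group above the bottom group's mean) and the common-language effect size
Φ(d/√2) (probability a random top-group member outscores a random
bottom-group member); the two transforms agree with the published
whole-percent values for d = 1.20, 0.64 and 0.80.

## Synthetic data

The generator emulates what the analysis consumes, not a demographic history:

* **Genotypes**: Gaussian-copula threshold model — per haplotype, a latent
  normal vector with block-diagonal AR(1) correlation (`corr(i,j) = ρ^|i−j|`
  within a block) is thresholded at Φ⁻¹(MAF). This gives exact, independent
  control of LD and allele frequency. Stratification, when enabled, draws
  per-subpopulation frequencies from a Balding–Nichols Beta around the
  ancestral MAF and shifts outcome means by subpopulation.
* **Effects**: point-normal architecture. One uniform draw per SNP is
  thresholded at each trait's causal fraction (causal sets are therefore
  nested across traits and identical for equal fractions); at causal SNPs
  effects are multivariate normal across traits with the configured
  genetic-correlation matrix; each trait's effects are rescaled so that
  β'Dβ = h² under the block LD — so realized heritability matches the
  configuration even with LD. Non-causal entries are exactly zero.
* **Summary statistics**: drawn per block from the sampling distribution
  `β̂ ~ N(Dβ, D/N)` on the standardized scale, SE = 1/√N, Wald p-values —
  statistically equivalent to per-SNP regressions on a simulated discovery
  cohort at a fraction of the cost. The info column is a constant 0.95
  (imputation error is not modelled). Panel alleles are drawn from
  non-palindromic pairs so default QC never silently removes simulated
  signal; ambiguous-allele handling is exercised by hand-built fixtures.
* **Outcome**: `y_i = Σ_t w_t g_it + e_i` with g the standardized true
  genetic values and Gaussian noise; the default configuration sets the noise
  variance equal to the genetic variance w'Rw (heritable share 0.5).

What passing synthetic tests do **not** show: robustness to genome-build or
id-scheme mismatches, realistic long-range LD or MAF/LD coupling,
imputation-quality variation, case–control ascertainment, or the behaviour of
real discovery GWASs with heterogeneous phenotype definitions. The synthetic
benchmarks establish internal correctness (oracle recovery, calibration,
directional behaviour), not real-data effect sizes.

## Defaults and problem sizes

| parameter | default | note |
|---|---|---|
| causal fractions | 1, 0.1, 0.01 | score variants per GWAS |
| Gibbs sweeps | 100 burn-in + 500 kept | stable posterior means at desk scale |
| LD window | simulation block size (50 SNPs) | windowed LD, zero across windows |
| principal components | 5 (synthetic) | 30 is the real-data convention |
| α grid | 0, 0.1, …, 1.0 | λ: 100 points, λ_max → λ_max·10⁻³ |
| CV | k = 10, repeats = 5 | 100 repeats for full-scale final runs |
| split | 60% train / 40% test | shared by all models |
| permutations | 100 000 | reference benchmark uses 20 000 |
| QC | MAF ≥ 0.01, info > 0.70, drop A/T & C/G | boundaries: MAF = 0.01 kept, info = 0.70 dropped |

The reference benchmark scenario (used by `scripts/acceptance.py` and the
acceptance tests) is 2000 target individuals × 3000 SNPs in 60 LD blocks
(ρ = 0.5), 10 discovery GWASs of N = 50 000 with single-factor genetic
correlations (pairwise ≈ 0.3–0.7), h² = 0.5, and an outcome built from three
traits at heritable share 0.5; the directional comparison runs 10 seeded
replicates with a 5-point α grid, 30 λ values, 2 CV repeats and B = 20 000
permutations so the whole script finishes in minutes on one CPU. The
parameter-recovery run raises discovery N to 5 × 10⁶ so the scores are
essentially noise-free and test R² can approach the heritable share.

## Numerical choices and degenerate inputs

* Monomorphic SNPs are excluded from LD and PCA with a warning (identity LD
  rows, zero standardized dosage).
* Estimated LD windows are regularized to PSD by diagonal inflation when the
  smallest eigenvalue is below −1e−8.
* Sub-seeds for every random stage derive from the global seed via a
  CRC32-based hash of the stage name, so adding or reordering stages does not
  silently change unrelated stages' randomness; identical configs reproduce
  all artifacts byte-for-byte.
* Constant predictions define correlation-R² as 0 (with a warning); constant
  score columns and degenerate splits raise.
* PCA uses exact SVD for small matrices and a deterministic Lanczos start
  (`svds`) for large ones; component signs are fixed by making each
  component's largest-magnitude loading positive.
* Fraction-selection ties go to the sparsest prior; hyperparameter ties to
  the largest λ.

## Limitations

* Matching is by marker id only — no positional liftover, no frequency-based
  strand inference for palindromes (they are dropped by default).
* h² for the shrinkage prior must be supplied (it is known in simulation);
  LD-score-regression estimation is out of scope.
* Windowed LD ignores cross-window and long-range LD; no reference-panel
  management beyond the target panel itself.
* Quantitative outcomes only; no logistic elastic net or liability-scale
  conversions.
* Genotype input formats: the generator's VCF (hard calls or dosages via
  cyvcf2); PLINK binary triplets are not read.
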