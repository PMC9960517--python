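# Methods

## The problem and the procedure

Clumping + thresholding (C+T) polygenic risk scores are notoriously
unstable on cohorts of modest size: the SNP content of the score depends
strongly on which samples happen to land in the training split. `iterprs`
implements a resampling-based stabilization of C+T:

1. **Iterative derivation.** The dataset is split `n_iter` times (default
   100) into an 80% source (training) and 20% target (testing) set. On each
   training set, principal components are recomputed and per-SNP summary
   statistics are derived with every registered association engine; on each
   test set a C+T search (greedy LD clumping at r² ≤ 0.1 within 250 kb,
   then a p-value threshold grid) picks the best single-split score. The
   per-iteration best test-set PRS R² values form the **baseline
   distribution** — the empirical null of what one unaggregated derivation
   achieves.
2. **Engine selection.** Engines are ranked by mean per-iteration PRS R²;
   the best engine's iteration results feed aggregation.
3. **Aggregation.** Each variant's appearances across the per-iteration
   models are counted; variants appearing at least `min_freq` times
   (default 5) are retained with weight equal to the mean of their training
   betas over the iterations where they appear.
4. **Candidate scan.** For every observed appearance frequency `f`, the
   variants with count ≥ f form a candidate score (so candidates are
   nested, shrinking as f grows). Each candidate is evaluated on the stored
   test splits and summarized by its mean incremental R², which is
   penalized for model size: `R_P² = R² / log N` with N the SNP count.
5. **Selection.** Each candidate carries an empirical bootstrap p — the
   fraction of baseline R² values exceeding its mean R². Candidates that do
   not maintain significance against the baseline (bootstrap p > 0.05 by
   default) are set aside; if none qualify, the minimum-p candidates are
   kept. Among the kept candidates, local maxima of the penalized curve are
   detected and the highest penalized R² wins, ties resolving toward fewer
   SNPs. The significance condition matters: the penalized metric divides
   by `log N` and therefore strongly rewards very small models, which on
   data with a few strong loci can have high `R_P²` yet be no better than a
   routine single-split derivation. Note that the base of the logarithm is
   a global constant across candidates (`log_b N = ln N / ln b`), so it can
   never change which candidate is selected; it is exposed only because it
   rescales reported values.
6. **Evaluation.** The final model is refitted on leave-out designs (5–50%
   of samples held out in 5% steps, several random holdouts per fraction)
   and on the whole dataset, always as the increment in R² between the
   covariate+PRS ("full") and covariate-only ("reduced") regressions.

### Key metrics

- **PRS.** `score_s = Σ_i w_i G_si / D`, G counting copies of the model's
  effect allele. The denominator D is configurable: twice the per-sample
  count of non-missing model variants (the per-allele average convention of
  common PRS tooling; the default), the literal sample count, or 1. On
  complete data the three are positive affine transforms of one another, so
  incremental R², regression p-values and min–max-normalized scores are
  identical across modes; the choice only affects the raw scale.
- **PRS R².** `R²(y ~ covariates + PRS) − R²(y ~ covariates)`, computed by
  residualizing on the covariate block (Frisch–Waugh–Lovell), which is
  algebraically identical to the two-regression difference and never
  negative for nested OLS fits.
- **Bootstrap p.** `#{baseline R² > candidate mean R²} / n_iter`.

## Upstream stages

**Harmonization and merging.** Variants shared between two cohorts are
compared by id and position (a positional conflict is a hard error) and
sorted into: identical; strand flip (alleles complemented, dosages
unchanged); allele switch (order reversed, dosage d → 2−d); flip+switch;
or dropped. Palindromic A/T and C/G pairs are ambiguous under flipping and
are always dropped. An optional offline allele-authority table (variant id
→ risk allele) can rescue otherwise unresolvable variants; it is the
hermetic stand-in for online annotation lookups. Merged output holds the
union of samples × retained variants with cross-cohort blocks missing.

**Imputation.** Two passes close the missingness the union creates:
(1) regression imputation — each incomplete variant is regressed on its
`window_snps` (default 10) nearest fully-observed neighbors on the same
chromosome, predictions accepted when the fit R² ≥ `r2_min` (default 0.8)
and rounded to hard calls in {0,1,2}; passes repeat (≤ `max_rounds` = 10)
because columns completed in one pass become predictors in the next;
(2) k-nearest-neighbor fill — remaining holes take the modal dosage of the
k = 10 nearest samples observed at that variant, distance being the mean
absolute dosage difference over mutually observed variants. The window,
R² floor and k are conventional values for these neighbor-based schemes;
reference-panel haplotype imputation is out of scope, and a pre-imputed
dataset with INFO scores is accepted instead.

**QC.** Filters run in the order INFO ≥ 0.9 (skipped without INFO scores),
SNP call rate ≥ 95%, MAF ≥ 5%, sample call rate ≥ 90%, then — as a second
round on the survivors — exact Hardy–Weinberg p ≥ 1e-9. The HWE test is
the exact conditional enumeration computed by recurrence in log space;
the chi-square approximation is unusable at the 1e-9 tail. HWE is applied
to all samples; restricting it to controls is a known alternative in
case-control designs but is not what this pipeline models.

**Stratification.** Dosage columns are centered at 2p and scaled by
√(p(1−p)); under binomial sampling each scaled column then has variance 2,
a constant that cancels everywhere it matters. The number of significant
PCs is chosen by sequential Tracy–Widom testing: at each step the
remaining spectrum's first two moments give the effective marker count
n̂ = (m′+1)S₁²/((m′−1)S₂−S₁²), the leading eigenvalue is normalized to
ℓ = m′λ/S₁, centered with μ = (√(n̂−1)+√m′)²/n̂ and the matching σ, and
compared to the TW1 critical value at α (default 0.05); testing stops at
the first non-significant eigenvalue. The n̂ moment estimator is the main
under-specified numerical detail of this construction and is the de facto
standard. Critical values come from an embedded quantile table
(log-interpolated); the 0.05/0.01/0.001 entries are the classical
published thresholds and the remaining grid points derive from the Chiani
shifted-gamma approximation of TW1, which doubles as an independent
cross-check in the tests. PCA is recomputed inside every training split by
default (`pca_mode="per_split"`), since summary statistics are derived de
novo per iteration; a single global PCA is available as a flag.

**Association.** Two mathematically distinct engines stand behind one
interface: a Wald OLS t-test of the dosage coefficient, and a score (Rao)
test using the null-model residual variance with a 1-df chi-square. Both
are exact per-variant regressions computed via one QR of the covariate
block plus vectorized per-column algebra; they agree asymptotically but
differ at small n, which is what makes the engine comparison non-trivial.
Externally produced summary-statistic tables can be supplied as an
additional engine at the `derive` stage. Per-variant missing dosages are
handled by casewise deletion.

## The synthetic cohort generator

The generator is the package's study system: every quantity the pipeline
estimates has a planted truth.

- **Genotypes.** Per variant, an ancestral allele frequency is uniform on
  `maf_range` (default 0.05–0.5). With `n_pops > 1`, population-specific
  frequencies follow the Balding–Nichols construction
  `Beta(p(1−F)/F, (1−p)(1−F)/F)` at differentiation F = `fst`. Haplotypes
  are thresholded stationary AR(1) Gaussians (lag-1 correlation `ld_rho`,
  default 0.3, reset at chromosome boundaries), giving adjacent-variant LD
  so clumping and neighbor-based imputation have structure to exploit.
  Allele pairs are drawn from non-palindromic combinations only, so strand
  flips are always resolvable in simulated merges; palindromic handling is
  exercised by hand-built fixtures instead.
- **Phenotype.** Causal effects are N(0, h²/n_causal) on the standardized
  genotype scale, then de-standardized. Covariates (sex, age, two binary
  statuses) enter additively with modest defaults (~15% of phenotypic
  variance in total). Gaussian noise variance is solved from the realized
  genetic and covariate variances so that var(genetic)/var(total) equals
  the target h²; with this definition both the plain regression of
  phenotype on the true genetic score and the covariate-adjusted
  incremental R² of the true-causal model estimate h². If the drawn
  effects are so small that the non-genetic budget cannot absorb the
  covariate variance (likely only at very small `n_causal`), the noise
  floor is clipped and a warning reports that realized heritability falls
  below target.
- **Randomness.** A single integer master seed fans out into named
  substreams (genotypes, effects, noise, missingness, covariates, split,
  evaluate, ...) via hashed spawn keys, so any stage can be reproduced in
  isolation and full runs are byte-deterministic.

What the generator does **not** emulate: realistic human LD maps and
recombination hotspots, MAF–effect-size coupling, non-Gaussian phenotypes,
genotyping batch effects, relatedness, and reference-panel imputation
errors beyond a supplied INFO column. Passing tests therefore demonstrate
the pipeline's internal correctness and its behavior under a clean additive
architecture, not performance on real array data.

## Problem sizes and numerical choices

The acceptance computation runs the full study conditions (n = 2000
samples, m = 5000 variants, 50 causal, h² = 0.3, 100 iterations); unit and
property tests use cohorts of 200–2000 samples and 20–5000 variants chosen
so each check isolates one mechanism. The PCA Gram matrix is accumulated in
float32 (eigendecomposition in float64); all regression algebra is float64.
Ties in the C+T threshold scan resolve toward the stricter threshold;
plateau ties in local-maxima detection report the smallest model;
`select_final` ties prefer fewer SNPs. Degenerate inputs are handled
explicitly: monomorphic variants are skipped by PCA and association,
constant score vectors min–max-normalize to 0.5 with a warning, and a
sample sharing no observed variant with any neighbor falls back to cohort
modal dosages.

## Known limitations

- On architectures where a handful of loci carry strong signal, a single
  C+T derivation already captures most of the heritable variance; the
  aggregated score still improves on the baseline mean, but its advantage
  over the *best* of many baseline draws is bounded by test-split sampling
  noise, and the empirical bootstrap p may be small without being exactly
  zero. The stabilization advantage is largest in the weak-per-SNP-signal
  regime the procedure was designed for.
- Regression imputation accepts in-sample fit R² as its quality gate and
  rounds to hard calls; it will under-fill in weak-LD regions by design,
  delegating to the kNN pass.
- The engine comparison ranks by mean PRS R² only; no uncertainty is
  attached to the ranking itself.
- Binary traits, mixed models, kinship filtering and Bayesian shrinkage
  weights are out of scope.
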