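# Methods

## Model

For one genomic region with n individuals and p SNPs, let X be the genotype
matrix and y the phenotype, both standardized columnwise to mean 0 and
variance 1 with the divide-by-n convention, so xⱼᵀxⱼ = n and yᵀy = n exactly.
The trait model is linear with a sparse sum-of-single-effects structure:

    y = Xb + e,  e ~ N(0, σ² Iₙ),
    b = Σ_{l=1}^{L} γ_l b_l,  γ_l ~ Mult(1, π_l),  b_l ~ N(0, σ_bl²).

Each component l explains exactly one causal SNP; L only needs to upper-bound
the number of signals. The p × m annotation matrix A enters through the prior
causal probabilities via a softmax with component-specific random effects:

    π_lj = exp(Aⱼᵀw_l) / Σ_{j'} exp(Aⱼ'ᵀw_l),   w_l ~ N(0, σ_wl² I_m).

Treating the annotation weights as random effects with an estimated variance
is the central modeling choice: with hundreds of annotations and effectively
one categorical observation per component, fixed-effect weights overfit and
manufacture false positives, whereas the random-effects variance σ_wl² lets
the data decide how much annotation information to admit. With w_l ≡ 0 the
model is exactly the plain sum-of-single-effects regression.

### Assumptions

- Covariates (age, sex, principal components) are already regressed out.
- One region at a time; the L components are a-priori independent.
- In summary mode, the LD matrix matches the z-scores (in-sample or a close
  reference panel) and is near-PSD; SNP order is identical across files.
- Annotations may be continuous (standardized) or binary (centered). No
  intercept column is used — the softmax is invariant to a shared shift of
  all logits, so an intercept is unidentifiable.

## Inference

The marginal likelihood is doubly intractable: the softmax normalizer blocks
integration over w_l, and the combinatorial γ̃ blocks the rest. The
normalizer is bounded by a double-majorization (quadratic) upper bound

    log Σⱼ e^{aⱼ} ≤ ρ + Σⱼ [ (aⱼ−ρ−ξⱼ)/2 + λ(ξⱼ)((aⱼ−ρ)² − ξⱼ²) + log(1+e^{ξⱼ}) ],

with λ(ξ) = tanh(ξ/2)/(4ξ), λ(0) = 1/8, per-SNP parameters ξ_lj ≥ 0 and a
scalar ρ_l per component. This makes the bound-augmented complete-data
likelihood exponentiated-quadratic in w_l, so under the mean-field family

    q(b̃, γ̃, w̃) = Π_l q(b_l | γ_l) q(γ_l) q(w_l)

every coordinate update of the evidence lower bound F(q, Θ) is closed-form:

- **q(b_l, γ_l)**: a Bayesian single-effect regression on the residualized
  Xᵀ(y − X E[b₋l]), computed purely from (XᵀX, Xᵀy); the per-SNP prior enters
  as logits Aⱼᵀμ_{w_l} (the bound's normalizer terms are constant in j and
  cancel in the softmax normalization).
- **q(w_l)**: Gaussian with precision I/σ_wl² + 2 Σⱼ λ(ξ_lj) AⱼAⱼᵀ and mean
  Σ_w Σⱼ (α_lj − ½ + 2λ(ξ_lj)ρ_l) Aⱼ. The closed form is certified in the
  test suite by a numerical-gradient check of the bound-augmented objective.
- **ξ_lj** = √(E[(Aⱼᵀw_l − ρ_l)²]) (the bound's tightness condition) and
  ρ_l = (Σⱼ 2λ(ξ_lj)Aⱼᵀμ_wl + (p/2 − 1)) / (Σⱼ 2λ(ξ_lj)), the exact
  minimizer of the expected majorizer given ξ. The pair is alternated to a
  fixed point (each sweep costs O(p)); a guarded 1-D numerical fallback runs
  if the closed form ever failed to lower the majorizer.
- **σ²** = E_q‖y − Xb‖²/n, computed through sufficient statistics with the
  standard decomposition of the expected residual sum of squares.

### Variance-component estimation

σ_bl² and σ_wl² are estimated by **direct evidence maximization** rather than
the one-step moment updates σ_bl² ← Σⱼ α_lj(μ² + var) and
σ_wl² ← (‖μ_w‖² + tr Σ_w)/m. Both forms maximize F; the moment form is the
exact coordinate maximizer with q held fixed, but when a component carries no
signal it decays the variance only geometrically, so the ELBO keeps creeping
by more than any reasonable tolerance for the entire iteration budget. The
package instead maximizes, per component, the attained block maximum of F:

- for σ_bl², the single-effect log evidence
  log Σⱼ exp(prior_logitⱼ + logBFⱼ(σ_bl²)), optimized by bounded scalar
  search and compared against the σ_bl² → 0 boundary (null component);
- for σ_wl², the Gaussian evidence of the bound-augmented linear model,
  −(m/2)log σ² − ½ log det(D + I/σ²) + ½ cᵀ(D + I/σ²)⁻¹c with
  D = 2Σⱼλ(ξ_lj)AⱼAⱼᵀ, via one eigendecomposition of D per update.

Setting q to the exact conditional posterior at the optimized variance makes
each step a joint block-coordinate maximization, so the bound still never
decreases — this is enforced at runtime (any within-stage ELBO drop > 1e-4
raises) and tested across random fits.

The moment-update forms remain available as `update_variance_components` and
are unit-tested against their defining identities and a Monte-Carlo oracle.

### Three-stage fitting

1. **Stage 1** fits the annotation-free model (uniform prior logits),
   estimating σ², σ_bl² and q(b̃, γ̃).
2. **Stage 2** freezes each q(γ_l) at its stage-1 mean α_l and iterates the
   q(w_l), (ξ_l, ρ_l) and σ_wl² updates.
3. **Stage 3** runs the full joint coordinate ascent from the stage-2 state:
   per iteration, all single-effect updates (with prior logits A μ_wl), then
   all annotation-weight blocks, then σ².

Each stage stops when the ELBO changes by less than `elbo_tol` (default
1e-4) or after `max_iter_per_stage` (default 100) iterations; defaults are
L = 10 components. With no annotations (absent A, or all columns constant
and dropped), stages 2–3 are exact no-ops and the output is identical to
stage 1 — the plain sum-of-single-effects special case.

### Shrinkage behavior and what to expect from annotations

Each component contributes roughly one categorical observation toward m
annotation weights, so at a single locus the evidence for σ_wl² is weak and
the estimated annotation effect is often shrunk to (near) zero — the
quadratic bound, whose slack grows with the posterior variance of the
logits, shrinks even more aggressively than the exact evidence would. The
practical consequences, all reflected in the test suite:

- false-discovery control is preserved under high-dimensional annotations
  (the headline calibration property);
- power with annotations is never materially below the annotation-free
  power, but at these per-locus sample sizes the paired gain is frequently
  zero rather than positive;
- annotation *ranking* is much more robust than annotation *magnitude*:
  the importance score FIⱼ = max_l μ²_{w_lj} recovers a strong sparse
  annotation in the top 5% in the vast majority of replicates even when the
  absolute weights are tiny.

## Posterior summaries

- **PIP(j)** = 1 − Π_l (1 − α_lj), accumulated with log1p.
- **Global FDR selection**: local fdr(j) = 1 − PIP(j) sorted ascending (ties
  by index), running mean FDR(i), step-up selection of the longest prefix
  with FDR ≤ η. Step-up (not first crossing) because the running mean is not
  monotone in general.
- **Credible sets**: per component, the smallest prefix of the sorted α_l
  with mass ≥ δ (default 0.95). Components with max α_lj ≤ 2/p are treated
  as excess and not reported. When an LD matrix is available, sets with
  minimum absolute pairwise correlation below a purity threshold (default
  0.5; 0 = off when no LD is given) are discarded; both behaviors are
  exposed because the underlying method's convention is not fixed.
- **Annotation importance**: FIⱼ = max_l μ²_{w_lj}; ranking with ties broken
  by annotation order; the top 5–10% are flagged as potentially relevant.

## Synthetic-data generator

The generator emulates the benchmark design used to evaluate the method:

- **Genotypes**: two latent Gaussian haplotypes with AR(1) (default ρ = 0.5)
  or block-equicorrelated structure, thresholded at per-SNP MAF quantiles
  (MAF ~ U(0.05, 0.5)) and summed to dosages {0, 1, 2}, then standardized.
  The realized adjacent-dosage correlation matches the thresholded-Gaussian
  value computed by numerical integration (tested). This is a synthetic
  stand-in for real biobank genotypes: it reproduces controllable local LD
  but not long-range LD, allele-frequency/LD coupling, or realistic
  haplotype block boundaries.
- **Annotations**: A_jk ~ N(0, 1) i.i.d.; a ⌈sparsity·m⌉ subset of weights
  drawn w_k ~ N(0, w_var) (defaults: sparsity 1, w_var 0.01), the rest
  exactly zero. Real annotations are correlated and partly binary; the
  generator's independence is the benchmark's own idealization.
- **Causal SNPs**: π = softmax(Aw); the L0 causal SNPs (default 2) are
  chosen greedily by descending π subject to pairwise |genotype correlation|
  < 0.1. Greedy descent is the simplest deterministic reading of
  "highest π with pairwise correlation below 0.1".
- **Phenotype**: b₀ ~ N(0, h²/L0 · I) with regional heritability
  h² = 0.0075; noise variance (1−h²)/h² · Var(X₀b₀) is scaled to the
  *realized* genetic variance so the expected realized heritability is h²
  (tested over 200 draws); y is standardized and marginal z-scores computed.

Because causal SNPs are selected as the top-π SNPs rather than resampled
from π, the association between annotations and causality is stronger than
the raw w ~ N(0, w_var) would give — the generator reproduces that selection
exactly.

**Benchmark metrics**: empirical FDR = 1 − TP/discoveries (defined as 0 when
nothing is selected, with such replicates kept in the aggregate); power =
fraction of true causal SNPs above a PIP threshold; annotation selection
power = |relevant ∩ top|/|relevant| and FPR = |irrelevant ∩ top|/|irrelevant|
(the standard definitions; an alternative reading that divides the count of
relevant-in-top by the irrelevant total is internally inconsistent with
"false positive rate" and is not used). Aggregates pool discoveries across
replicates with binomial standard errors.

## Numerical choices

- Variances floored at 1e-10; α computed in log space with a stable
  log-sum-exp; λ(ξ) switches to its series 1/8 − ξ²/96 below ξ = 1e-4;
  log(1+e^ξ) via `logaddexp`.
- Σ_w kept dense (m × m) via Cholesky/eigendecomposition; O(m³) per
  component per iteration is acceptable for m up to a few hundred.
- Near-PSD LD matrices (min eigenvalue in (−1e-6, 0)) are eigenvalue-clipped
  at 0; anything more indefinite is rejected.
- Fitting is fully deterministic given inputs; all simulation randomness
  flows from a single master seed through spawned substreams.
- Monomorphic genotype columns and constant annotation columns are rejected
  and dropped-with-warning respectively.
- eFDR with zero discoveries is defined as 0 and logged.

## Benchmark problem sizes

The packaged benchmark and acceptance checks run at desk scale — n = 10 000
samples, p = 500 SNPs, m = 100 annotations, 50–100 replicates — which keeps
a full calibration run in the minutes range on one CPU while preserving the
qualitative regime (per-SNP z ≈ 6 at h² = 0.0075 with L0 = 2). Power-gain
checks amplify the annotation-weight variance to w_var = 0.02, the smallest
value on a coarse grid at which the top softmax probability averages at
least 20/p, and record the amplification explicitly; the sparse-recovery
check uses a single relevant annotation with w_var = 4 (weight s.d. 2), an
explicitly amplified "strong single annotation" setting.

## Known limitations

- Per-locus annotation evidence is intrinsically weak (one observation per
  component); the method's value with annotations grows with the number of
  signals and the strength of the annotation–causality coupling, and a
  per-locus fit should not be expected to estimate annotation weights with
  useful magnitude — only their ranking is stable.
- No multi-region joint fitting, no MCMC verification, no colocalization,
  no enrichment p-values for annotations.
- Summary mode trusts the supplied LD; mismatched reference panels are not
  detected beyond PSD validation.
- The credible-set purity filter and the near-uniform component rule are
  conventions, exposed in configuration and logged, not claims about the
  underlying method's exact reporting rules.
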