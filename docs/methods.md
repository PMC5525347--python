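# Methods

## Model and decision rule

All procedures operate on the linear model Y = Xβ + ε, ε ~ N(0, σ²Iₙ), with
the n×p genotype matrix standardized columnwise to mean 0 and variance 1
using the population (1/n) denominator, so that xⱼ'xⱼ/n = 1 exactly, and Y
centered (the intercept is handled by centering and never penalized). The
Lasso estimate minimizes

    (1/(2n)) ‖Y − Xβ‖² + λ‖β‖₁ .

On this scale the penalty is commensurate with the marginal statistics
xⱼ'Y/n; the conversion to the unscaled objective is λ_unscaled = n·λ.
The common decision rule is: declare SNP j significant iff β̂_{λ,j} ≠ 0.

The error-control argument runs through the coordinate-wise fixed point:
β̂_{λ,j} ≠ 0 iff the partial-residual statistic β̂ⱼᴼᴸˢ = (1/n)Σᵢ xᵢⱼ rᵢ₍ⱼ₎
exceeds λ in absolute value, and under a global null β̂ⱼᴼᴸˢ ≈ N(0, σ²/n).
The penalty with per-SNP type-1-error α is therefore the quantile
λ_α = z₁₋α/₂·σ/√n. This is exact for independent SNPs and conservative
under positive dependence; it is the package's acceptance surface, not the
HapMap-correlated null structure used in the original empirical tables.

## Penalty selectors

**Permutation selection (s-sparse variant, α ≥ 1/p).** Permute Y, then
bisect on [0, λ_max] for the largest λ whose fit on the permuted data has
exactly s = round(α·p) nonzero coefficients (reported back as the attained
level s/p). Averaging B independent replicate estimates gives λ̄_α with
Var(λ̄_α) = Var(λ̂_α)/B; B=1 is the single-permutation (Ayers) selector.
Replicate sub-seeds derive deterministically from the master seed, so
results are independent of scheduling and fully reproducible.

**Permutation selection (k-max variant, α < 1/p).** With α = 1/(p·k), the
k·p marginal null statistics |xⱼ'Y_perm|/n from k permutations are pooled;
any penalty between their largest and second-largest values leaves exactly
one of the pooled null coefficients nonzero. The *midpoint* of that
interval is used. This is a deliberate numerical choice: the midpoint is
the Hazen empirical-quantile estimator at level 1 − 1/(k·p) and is
essentially unbiased for the target quantile z₁₋α/₂·σ/√n, whereas the
upper endpoint (the strict maximum of the pooled statistics) overshoots it
by ≈7% at k·p = 100, which measurably depresses power.

**Analytic selection.** For each λ on a grid (200 log-spaced points over
[0.3, 1.5]·λ_guess, λ_guess = z₁₋α/₂·sd(Y)/√n), fit the Lasso, estimate
σ̂²(λ) = RSS/(n − df) with df = number of nonzero coefficients, and compute
the estimated per-SNP error ê(λ) = 2Φ(−√n·λ/σ̂(λ)). The selected λ
minimizes |ê − α|, preferring the conservative side on ties; a warning
carries the full profile when no grid point comes within 10α of α. The
residual-variance estimator is the standard Lasso degrees-of-freedom
choice and is recorded in the output profile; selected penalties are
implementation-sensitive at the third decimal.

## Resampling tests at a fixed penalty

λ is chosen once by 10-fold cross-validation (seeded random folds, plain
CV-error minimiser — no one-standard-error rule; 100 log-spaced grid from
λ_max down to 1e-4·λ_max for n > p, 1e-2·λ_max for p ≥ n where the
unpenalized limit is ill-posed) and held fixed throughout.

**Residual bootstrap.** Center the residuals of the fit, resample them
with replacement, rebuild Y* = Xβ̂_λ + e*, refit at the same λ, and form
reflected (basic) percentile intervals CIⱼ = (2β̂ⱼ − q*₁₋α/₂, 2β̂ⱼ − q*α/₂);
reject where 0 ∉ CIⱼ. Quantiles use linear order-statistic interpolation
(numpy default); B must satisfy α/2 ≥ 1/B (defaults: B = 1000).

**Modified residual bootstrap.** Identical machinery around the
hard-thresholded vector β̃ⱼ = β̂ⱼ·1(|β̂ⱼ| > τ): residuals are taken from the
thresholded fit, centered *after* thresholding, Y** = Xβ̃ + e**, interval
(β̂ⱼ + β̃ⱼ − q**₁₋α/₂, β̂ⱼ + β̃ⱼ − q**α/₂). τ = 0 reduces exactly to the
plain bootstrap; a τ sweep preset {0.001, 0.005, 0.01, 0.03, 0.05} is
provided.

**Permutation test.** B permutations of Y, refit at the fixed λ, and
pⱼ = (#{|β̂ᴾⱼ| ≥ |β̂ⱼ|} + 1)/(B + 1) (default B = 999, so α = 0.01 is
attainable exactly). The as-extreme-or-more (≥) convention is identical to
the strict (>) one for continuous statistics but differs on the Lasso's
atom at zero: a SNP never selected in the observed fit ties with every
all-zero permutation fit and receives p = 1, not the floor 1/(B+1). The
strict convention would declare every never-selected null significant
under heavy penalties, which is plainly not the intended test.

Bootstrap and permutation refits reuse warm starts; results are
warm-start-independent at the KKT tolerance.

## Solver

Cyclic coordinate descent with soft thresholding, in two variants: a
residual-updating kernel working directly on X, and a covariance-updating
kernel on a precomputed Gram matrix G = X'X/n that is shared across the
many refits with different responses (permutations, bootstrap draws,
bisection). Both use an active-set strategy (full sweep, then sweeps over
the nonzero set until stable, repeated until a full sweep moves no
coefficient by more than the tolerance). Inference fits use tolerance
1e-7 on the maximum coefficient change (needed to resolve nonzero counts
near knots of the path) with at most 1e5 sweeps; non-convergence raises an
error carrying the attained KKT violation. The Gram variant is used by
default up to p = 4000.

Bisection for an exact nonzero count brackets [λ with count ≥ s, λ with
count < s], halves to a width of 1e-6·λ_max (≤ 100 halvings), and returns
the largest qualifying λ; when several coefficients enter simultaneously
and exactly s is unattainable, the smallest bracketed penalty with count
≤ s is returned and the discrepancy logged — conservative in the direction
of fewer discoveries.

## Synthetic data

Independent mode draws each SNP as Binomial(2, maf) (Hardy–Weinberg
marginals) with MAFs uniform on (0.05, 0.5) — only common variants.
LD-block mode uses a one-factor latent Gaussian copula per block: a latent
anchor variable, neighbor latents correlated with it, all thresholded at
the Hardy–Weinberg cut points so marginals stay Binomial(2, maf). The
latent correlation needed to hit a requested genotype r² is found by
inverting the exact thresholded-bivariate-normal moment (brentq on the
rectangle-probability expression). Neighbor MAFs are drawn within ±15% of
the anchor's (log scale): SNPs in strong LD share allele frequencies, and
the maximal attainable genotype correlation shrinks as MAFs separate.

The baseline power scenario is 600 subjects, five independent causal SNPs
with standardized effect 0.15 each and σ = 1, so each causal SNP explains
≈2% of trait variance (total R² ≈ 0.10), with 0–20,000 additional null
SNPs. The region scenario keeps five blocks of one latent causal SNP plus
ten neighbors (per-neighbor r² targets uniform on (0.05, 0.6), mean ≈ 0.3,
bracketing the 0.18–0.33 per-region means of the reference design), plus
950 independent nulls; after phenotype generation the causal columns are
removed and each retained SNP's signed correlation with each latent causal
SNP is recorded for region-level scoring with cutoffs τ_LD ∈ {0.3, 0.5}.

What the generator does *not* emulate: real haplotype block structure
(recombination hotspots, allele-frequency/LD coupling beyond the one-factor
copula), case-control ascertainment, missingness, or the weak long-range
correlation present in a real chromosome's "independent" nulls. Passing
tests therefore demonstrate correctness of the inference machinery under
the stated generating model, and the independence-design error-control
theory; they do not certify error rates under real LD, where permutation
selection is expected to be conservative.

## Scoring

Marker-level: TPR = fraction of causal SNPs rejected, FPR = fraction of
null SNPs rejected, per replicate, averaged with Monte-Carlo standard
errors sd/√n_reps (reported explicitly as standard errors — rates and
their uncertainties are labelled separately in the output). Region-level:
a SNP is linked when |r| ≥ τ_LD to some latent causal SNP (the sign of r
is irrelevant for tagging); a region counts as detected when at least one
of its linked SNPs is rejected; LTPR is the rejected fraction of all
linked SNPs; FPR is the rejected fraction of SNPs linked to no region.
Regions with no linked SNP at the chosen cutoff are excluded from the TPR
denominator with a warning.

## Problem sizes used by the checks

The shipped test suite and acceptance script regenerate everything from
seeds: 300 replicate datasets for the power and penalty comparisons; 100
replicates of a 600×1000 independent global null for error-rate control
(B = 50); 1000 replicate datasets (30 bootstrap draws each) for the
bootstrap-distribution match, where the two-sample KS statistic's null
expectation (~0.027) sits well inside the 0.05 acceptance bound; 20
replicates at 2000 null SNPs for the high-dimensional degradation
comparison; and 200 runs per B ∈ {1, …, 32} on a fixed 600×200 null for
the 1/B variance law. These sizes were chosen so every distributional
check has its Monte-Carlo noise well below the tolerance it asserts.

## Known limitations

- Significance levels are restricted to s/p or 1/(p·k); the attained level
  is always reported alongside the requested one.
- The selectors provide decisions with (approximate) error control, not
  p-values or confidence intervals; the bootstrap provides intervals but
  is unreliable once null predictors are numerous.
- The analytic selector's σ̂ choice (RSS/(n − df)) is one of several
  defensible estimators; alternatives shift the selected penalty in the
  third decimal.
- Cross-validated fold fits use a relaxed coordinate tolerance (1e-4);
  held-out MSE is insensitive to it, but fold-level coefficient values are
  not resolved to inference precision.
- With p ≥ n the CV grid floors at 1e-2·λ_max; penalties below that are
  never candidates (the dense sub-floor path is ill-posed and numerically
  unstable anyway).
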