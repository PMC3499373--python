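# Methods

## Model and assumptions

The package analyzes a region of m biallelic variant sites, coded as
minor-allele counts g ∈ {0,1,2}ᵐ per individual, in a sample selected
because the primary quantitative trait Y₁ fell in a two-sided tail
region (Y₁ ≤ lo or Y₁ ≥ hi). Traits are modelled as linear in genotypes
and covariates with bivariate-normal residuals:

    Y₁ = X₁γ₁ + Σⱼ βₚⱼ gⱼ + ε₁        sd σ₁
    Y₂ = X₂γ₂ + Σⱼ βₛⱼ gⱼ + ε₂        sd σ₂,  corr(ε₁, ε₂) = ρ

Assumptions: ascertainment depends on Y₁ only; residuals are normal;
sites enter additively (no dominance or interactions); the selection
region is known (or recoverable as the innermost selected values per
tail, which at thousands of selected individuals is indistinguishable
from the design cuts).

## Null model estimation

Under the null (no secondary-trait association), the ascertained
likelihood factorizes as f(y₁ | G, A=1) · f(y₂ | y₁, G). We
re-parameterize in (γ₁, βₚ, σ₁, γ₂, τ, σ₂|₁), with τ the coefficient of
the primary-trait residual in the conditional mean of Y₂ (population
value ρσ₂/σ₁), and maximize the two factors **jointly**:

* f(y₁ | G, A=1): normal density divided by the two-sided truncation
  normalizer Φ((lo−μ₁)/σ₁) + 1 − Φ((hi−μ₁)/σ₁);
* f(y₂ | y₁, G): normal with mean X₂γ₂ + τ(y₁ − μ₁) and sd σ₂|₁.

βₚ appears in both factors (through μ₁), and this matters. A two-stage
fit — truncated-normal regression for the primary trait, then OLS for
the conditional secondary model — is also provided
(`compute_residuals(..., method="two-stage")`) and is the natural
reading of the factorization, but it discards the second factor's
information about βₚ. The resulting estimation error is a fixed,
genotype-aligned offset in the residuals, and we measured it to inflate
the per-site statistics substantially (SKAT type-I ≈ 0.19 at α = 0.05
in the 5,000-of-100,000 design). The joint MLE instead orthogonalizes
the residuals against the nuisance directions, which errs slightly
conservative — the behaviour this family of methods is known for. The
joint fit is therefore the default.

### Genotype coding in the null fit

Each polymorphic site with MAF ≤ the VT cap (0.05) and minor-allele
count ≥ 10 enters the primary-trait mean as its own column; rarer sites
are collapsed into a single aggregate count column. Rationale: per-site
ML coefficients at minor-allele counts below ~10 are noise-dominated
(we measured 2–7× the Fisher-information variance), and that noise
leaks into the residuals; the aggregate column absorbs the rare sites'
average effect at one well-identified parameter. The threshold trades
per-site misspecification (uncorrected heterogeneity among ultra-rare
sites) against estimation noise; 10 is where the two measured error
contributions cross in our simulations. A user-supplied scalar or
matrix coding overrides this default.

### Optimization

L-BFGS-B on (coefficients, log σ) with analytic gradients, initialized
from OLS on the selected sample (two-stage estimates initialize the
joint fit). Tolerances: ftol 1e-11, gtol 1e-7; a BFGS restart runs on
non-convergence and the result is flagged if the gradient is not
numerically flat. The truncation normalizer uses complementary log-CDF
forms (`log_ndtr`) to avoid cancellation at extreme cuts, with the
log-normalizer floored at −700 so impossible parameter regions repel
the optimizer smoothly instead of producing NaNs. A ridge of 1e-6 on
coding coefficients keeps the fit defined when rare-variant columns are
exactly collinear (e.g. two singletons carried by the same individual).
σ estimates within 1e-8 of zero raise rather than returning a
degenerate fit.

## Tests and inference

All five region statistics operate on the null-model residuals e, with
per-site minor-allele frequencies estimated from the analyzed sample;
monomorphic columns never contribute. Burden scores are
U = Σᵢ eᵢ(xᵢ − x̄). WSS/Madsen–Browning weights use the pseudo-count
frequency estimator q = (c+1)/(2n+2) from the whole sample, so they
never depend on the trait. VT standardizes each threshold's burden
score by its exact permutation SD, √(Σ(e−ē)² Σ(x−x̄)²/(n−1)), and takes
the max of |z(t)|. SKAT uses the weighted linear kernel with the
squared Madsen–Browning weight by default (Beta(1,25)² optional). The
KBAC extension to quantitative traits groups individuals by their
distinct rare multi-site genotype and weights group k by
Φ(ē_k √n_k / σ̂) — the estimated probability that the genotype raises
the trait — recomputing the weights inside every permutation; it is a
reconstruction of the binary test's adaptive-weighting idea with
Gaussian tail probabilities in place of hypergeometric ones.

Permutation p-values shuffle the residuals only and use the add-one
convention (never zero; minimum 1/(B+1)). Burden-family tests are
two-sided; SKAT, KBAC and VT, whose statistics are non-negative
quadratics or maxima, use the upper tail. A vectorized engine evaluates
all five tests on one (B × n) permutation-index matrix: burden, SKAT
and VT permuted statistics are matrix products, KBAC group sums are
bin-counts. In the experiment harness the permutation matrix is drawn
once per run and reused across replicates — replicates are independent,
so the conditional p-values remain valid and i.i.d. — which removes
~40% of runtime.

Analytic p-values: a normal tail with the exact permutation variance
for burden scores, and the mixture-of-χ² tail (eigenvalues of the
centred weighted genotype cross-product scaled by the residual
variance) for SKAT, evaluated exactly for one eigenvalue, by Imhof's
numerical inversion otherwise, with Liu moment-matching as fallback.
Both are documented approximations; permutation is the primary
inference at rare-variant counts.

## Meta-analysis

Per-study p-values are transformed to Z scores and combined as
Z_meta = Σ√nᵢZᵢ/√Σnᵢ. Burden-family tests enter directionally
(Z = sign(U)·Φ⁻¹(1−p/2), two-sided meta p); SKAT/KBAC/VT enter
direction-free (Z = Φ⁻¹(1−p), upper-tail meta p). The Z transform uses
the **mid-p** permutation estimate (count+0.5)/(B+1): the add-one
estimator is valid but conservatively biased, and the bias compounds
√(#studies)-fold in the combination; the reported per-study p-value
remains the add-one estimator. p is clamped at 1e-15 before the
quantile transform; a p of exactly 1 is clamped with a warning.

## Synthetic data generator

The generator emulates the rare-variant architecture the method
consumes, not any particular population history. Site MAFs follow a
reciprocal (1/x) spectrum on [1e-4, 0.5] — the rare-skewed shape of a
neutral frequency spectrum — and genotypes are independent-site
Hardy–Weinberg binomial draws. Purifying selection is summarized by a
per-site coefficient s, with P(s > 1e-4) declining log-linearly in MAF
from 0.9 at MAF 1e-4 to 0.05 at MAF 0.5; deleterious sites (s > 1e-4)
form the causal-eligible pool. Causal sets for the two traits are
independent 50% draws from that pool, so their intersection is
pleiotropic. Effect magnitudes are constant (|β| = c1) or increase with
rarity (|β| = c1 + c2·|log₁₀ MAF|); a configurable fraction of causal
effects is positive. Regions default to 60 sites before
monomorphic-site filtering.

What this does **not** emulate: linkage disequilibrium, demographic
bottlenecks/expansions, recurrent mutation, genotyping error, family
structure, non-normal traits. Passing tests therefore show that the
ascertainment correction and the test statistics behave as designed
under the stated model — not that power estimates transfer to any real
gene, whose frequency spectrum and effect distribution differ. Hooks
(`sites_from_table`, externally supplied codings) let a forward
simulator replace the generator.

## Experiment designs and problem sizes

The type-I/power harness reproduces two designs: a single study
selecting 5,000 extremes from 100,000, and a three-study meta-analysis
each selecting 2,500 from 50,000 with primary effects (−0.5, 0.25, 0)
and trait correlations (0.6, 0.4, −0.2). The desk preset runs 500
replicates with 500 permutations (the full preset: 10,000 and 5,000).
The test suite uses 200–500 replicates and 200–500 permutations per
scenario, and smaller cohorts (20,000/1,000) for parameter-recovery
checks, with all Monte-Carlo assertions at 3 standard errors or exact
binomial bands for the replicate count actually used.

## Known limitations

* Slight conservativeness: the joint null fit orthogonalizes residuals
  against the fitted nuisance directions, so observed statistics are
  mildly deflated relative to their permutation reference. Single-study
  rejection rates at α = 0.05 land at ≈ 0.04–0.05; in the three-study
  meta-analysis the deflation compounds √3-fold and the combined VT
  rate drops to ≈ 0.02–0.03. The exact remedy — refitting the null
  model inside every permutation — costs B × replicates joint MLEs and
  is not implemented.
* The same orthogonalization absorbs a share of a true secondary-trait
  signal at pleiotropic sites (more so when carriers sit deep in one
  tail, where the two-sided-truncation information about their primary
  mean collapses). In our simulations this offsets the power gain from
  pleiotropic-carrier enrichment, so adding a primary-trait effect to a
  pleiotropic gene does not reliably increase power here.
* Naive-analysis bias (`naive_bias`) treats the genotype coding as
  Gaussian with the supplied variance — the tractable large-sample
  approximation; it is exact in ρ-linearity and the zero cases, and
  agrees with a 10⁷-individual brute-force simulation to < 1% at
  (βₚ = 0.5, ρ = 0.6, 5% tails).
* Missing genotypes are rejected, not imputed; multiallelic records
  must be split upstream; one-tailed ascertainment designs and binary
  primary traits are out of scope.
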