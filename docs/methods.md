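# Methods

## Model

For a gene containing m variants, let z = (z_1, …, z_m) be the GWAS
summary Z-scores of those variants, z_j = ln(OR_j)/SE_j oriented to the
reference panel's counted (ALT) allele, and let R be the m×m Pearson
correlation matrix of panel genotype dosages at the same variants. Under
the null hypothesis of no association, and for the large samples typical
of GWAS meta-analyses, z is modelled as multivariate normal with mean 0
and covariance R: the correlation between two variants' Z statistics
equals their linkage disequilibrium in the population, estimated here
from an external reference panel. This approximation is the basis of all
three tests and is the package's central assumption; it degrades when
the panel's LD does not match the study population's (the reason the
analyses this package supports are restricted to a panel matched in
ancestry).

Three gene-level statistics are computed:

* **Sum test (ST)** — B = Σ_j z_j, a burden-type statistic. Under the
  null B ~ N(0, 1ᵀR1); the two-sided p-value is the χ²(1) tail of
  B²/(1ᵀR1). Most powerful when effects share a direction.
* **Squared-sum test (S2T)** — Q = Σ_j z_j², a SKAT-type statistic. Its
  null is the weighted sum Σ_k λ_k χ²_k(1) with λ the eigenvalues of R.
  Robust to mixed effect directions.
* **Adaptive test (AT)** — the family Q_ρ = (1−ρ)Q + ρB², ρ ∈ [0, 1],
  interpolates between the two. Each Q_ρ is a quadratic form z'A_ρz with
  A_ρ = (1−ρ)I + ρJ, so its null weights are the eigenvalues of
  A_ρ^{1/2} R A_ρ^{1/2} (computed in closed form through the rank-one
  structure of A_ρ). T = min_ρ p(Q_ρ) over a grid, and the reported
  p_AT = P(min_ρ p_ρ ≤ T | z ~ MVN(0, R)) accounts for the minimization.

## Weighted-chi-square survival function

`quadform_sf(q, λ)` inverts the characteristic function numerically
(Imhof-type):

P(Q > q) = 1/2 + (1/π) ∫₀^∞ sin θ(t) / (t ρ(t)) dt,
θ(t) = ½Σ arctan(λ_k t) − ½qt, ρ(t) = Π (1 + λ_k²t²)^{1/4}.

The scalar routine splits the integral at t = 3 (after normalizing
λ_max = 1): adaptive Gauss–Kronrod on [0, 3], then the oscillatory tail
via QUADPACK's Fourier-weighted quadrature at the asymptotic frequency
q/2 (as t → ∞, θ(t) → mπ/4 − qt/2). Default absolute error 1e−9.
Degenerate weight patterns (single or all-equal eigenvalues) use the
exact chi-square closed form. When inversion fails to converge or yields
p < 1e−12 — beyond the resolution of an absolute-error inversion — the
routine falls back to moment matching in the style of Liu–Tang–Zhang: a
noncentral chi-square matched to the first moments and skewness (the
kurtosis-matched branch when s₁² ≤ s₂). The method actually used is
recorded on the result.

A vectorized variant evaluates many quantiles against one shared weight
vector with a midpoint rule plus a two-term integration-by-parts
correction for the truncated oscillatory tail; truncation is pushed to
t = 150 when fewer than five eigenvalues remain (slow envelope decay).
Stability is verified by node doubling and truncation extension, and
entries that fail to stabilize are recomputed by the scalar routine.
This path serves the inner loop of the adaptive test at an internal
tolerance of ~1e−7, ample against every tolerance used downstream.

## The min-p null probability

p_AT is computed by one-dimensional numerical integration, conditioning
on the standardized burden component — the same decomposition used by
optimal unified kernel-association tests:

* write z = a·u + w with u = 1ᵀz/√(1ᵀR1) ~ N(0,1), a = R1/√(1ᵀR1) and
  w ~ MVN(0, Σ_w), Σ_w = R − aaᵀ, independent of u;
* then Q_ρ = τ(ρ)u² + (1−ρ)(wᵀw + 2u aᵀw) with τ(ρ) = ρ·1ᵀR1 +
  (1−ρ)·aᵀa;
* per-ρ thresholds q_T(ρ) with sf(q_T(ρ)) = T are taken from the
  moment-matched (Liu-type) quantile, the standard practice in this test
  family — per-ρ p-values themselves use CF inversion;
* the residual κ = wᵀw + 2u aᵀw is approximated by the eigenvalue form
  of Σ_w rescaled to carry the extra cross-term variance
  4aᵀΣ_w a (thresholds are shrunk toward the mean by
  sd(κ₀)/sd(κ) before evaluating the CDF);
* P(all ρ: Q_ρ < q_T(ρ)) is integrated over the χ²(1) density of u²
  (Gauss–Legendre in u after the substitution x = u², 96 nodes; the
  ρ = 1 grid point enters exactly as an upper limit on u²), and
  p_AT = 1 − that probability.

A Monte-Carlo estimator of the same event — draws z* ~ MVN(0, R) by a
square-root factorization with diagonal jitter ≤ 1e−8, p̂ = (1 + #{any
Q*_ρ ≥ q_T(ρ)})/(N+1) — serves as cross-check and as automatic fallback
when integration diagnostics fail (non-finite value or probability
outside [0, 1]). Because per-ρ p-values are monotone in Q_ρ, comparing
in the Q domain against the shared thresholds makes the two routes
estimates of exactly the same probability. The reported p_AT is finally
clamped into the min-p sandwich [T, min(1, |grid|·T)], which holds by
construction for the true quantity.

The ρ grid defaults to the squares of an 11-point even grid,
(0, 0.01, 0.04, …, 0.81, 1): the optimum of the family usually sits
near the S2T end, where the squared grid is dense. A uniform grid can be
supplied instead. With m = 1 all statistics coincide and the χ²(1)
closed form is returned directly.

## Input processing

**Summary-statistics QC** applies, in fixed order so removal tallies are
reproducible: autosome filter; INFO (imputation-quality) filter, by
default keeping INFO ≥ 0.9 and records with missing INFO;
strand-ambiguous filter (allele pair A/T or C/G, unresolvable without
strand information); non-biallelic filter (multiple inconsistent allele
pairs at one site — all records at the site dropped); duplicate-rsID
filter (every record carrying a duplicated ID dropped). Z-scores are
then ln(OR)/SE, oriented to the effect allele.

**Gene assignment** uses TSS–TES intervals (1-based inclusive; BED's
0-based half-open convention converted on read). Membership is inclusive
at both ends with optional symmetric padding (default 0 — the gene body
alone). Overlapping genes each receive shared variants; per-gene tests
are marginal, so sharing introduces no double counting within a test.
Genes with fewer than 2 variants are dropped: a single variant cannot
support a set-level test beyond its own marginal chi-square.

**Harmonization** matches GWAS variants to panel variants by position
and allele pair; when the GWAS effect allele is the panel's REF allele
the Z sign is flipped, so every z counts the panel's ALT allele —
consistent with R computed from ALT-dosage correlations. Incompatible
allele pairs are dropped and counted. Strand-complement matching is
deliberately not attempted: ambiguous pairs were already removed, and
silent complement matching is a known source of sign errors.

**LD estimation** is the pairwise-complete Pearson correlation of dosage
vectors, with monomorphic variants dropped, the matrix symmetrized, and
the diagonal pinned to 1. **Pruning** removes the later-position SNP of
any pair with |r| ≥ 0.9999 (greedy in position order, earlier SNP kept
as the deterministic tie-break), then re-checks the survivor set. The
threshold is configurable; 0.9999 distinguishes genuinely redundant
variants from merely tight LD.

**Bundles** store each gene's SNP table and LD matrix as delimited text
(17 significant digits, re-read with round-trip float parsing), one
directory per chromosome plus a manifest with counts and SHA-256
checksums. Two writes of the same data are byte-identical.

## Differential-expression stage

A deliberately simplified two-group negative-binomial analysis:
median-of-ratios size factors (reference = per-gene geometric mean over
genes expressed in all samples; factors rescaled to geometric mean 1);
per-gene NB GLM with log link, design = intercept + condition, offset =
log size factors; dispersion per gene by method of moments on normalized
counts pooled across the two groups (floored at 1e−8) — chosen over
maximum likelihood because the emulated designs are as small as 3 vs 3,
where per-gene ML dispersion is unstable; Wald test on the condition
coefficient converted to log2; Benjamini–Hochberg adjustment over the
converged genes. The gene filter keeps genes with total count across all
samples ≥ 10. There is no dispersion shrinkage, no outlier handling and
no fold-change shrinkage; results are therefore not expected to match
shrinkage-based tools numerically, and the stage is validated on
synthetic data with known fold changes instead. Note that
median-of-ratios normalization assumes most genes are not differentially
expressed; validation scenarios in which *every* gene carries a fold
change supply the generator's true size multipliers to the GLM.

## Synthetic data

The generator produces every input the pipeline reads, as pure functions
of a seed. Genotype panels use a latent-Gaussian threshold model: per
haplotype, x ~ MVN(0, R_target); the variant carries the alternate
allele when x_j < Φ⁻¹(MAF_j); dosages are the sum of two haplotypes.
Dosage correlations are attenuated relative to R_target (the threshold
transform contracts dependence); this is accepted and measured rather
than corrected, because the pipeline estimates LD from the realized
panel exactly as it would with real data. Z-scores are drawn from
MVN(δ, R̃) with R̃ the realized panel correlation — alternatives are
mean shifts rather than simulated phenotypes, which suffices for
null/power structure at desk scale — and converted to files via
OR = exp(z·SE), SE ~ U(0.02, 0.05), INFO ~ U(0.92, 1). The effect-allele
column is randomly oriented to REF or ALT so harmonization is genuinely
exercised. Strand-ambiguous pairs are never generated.

Defaults mirror the emulated study conditions: a 503-sample panel (the
size of the 1000 Genomes phase-3 European subset), AR(1) LD with
r = 0.5, 10 SNPs per gene, common variants (MAF 0.05–0.5), and a 3 vs 3
expression design. What the generator does **not** emulate: real LD
block structure, allele-frequency spectra, imputation error, population
stratification, overlapping gene annotations, or count outliers — so
passing tests demonstrate correctness of the statistical machinery under
the model's own assumptions, not robustness to real-data pathologies.

## Validation problem sizes

The validation suite uses: 4,000 null genes for type-I calibration
(empirical rejection compared to the exact binomial 99% interval at
α = 0.05); 5×10⁵ draws for the weighted-chi-square oracle and 2×10⁵ for
the min-p oracle (agreement within 3 binomial SEs); 500 genes at n = 20
per group for fold-change recovery (±0.05) and 2,000 null genes at
n = 10 per group for p-value uniformity (KS < 0.08); and 100 replicated
end-to-end studies of 50 genes with one injected signal gene for the
detection experiment. The injected per-SNP shift is 3 — a clear signal,
chosen so the detection experiment has essentially full power and its
failure budget is spent on family-wise error control, which is the
property the experiment is designed to exercise.

## Numerical choices

* Correlation matrices are symmetrized as (R + Rᵀ)/2 before every
  eigendecomposition; eigenvalues are clipped at 0 (tolerance 1e−8 for
  genuine negativity, which raises an error) and eigenvalues below
  1e−12·λ_max are dropped from weight vectors.
* Square-root factorization for simulation tries Cholesky with
  escalating diagonal jitter up to 1e−8, then falls back to the
  eigendecomposition square root.
* p-values are floored at 1e−300 (reported in (0, 1], never exactly 0).
* 1ᵀR1 ≤ 0 (degenerate burden variance) raises a numerical error rather
  than returning a value.
* All stochastic paths take explicit seeds; the pipeline derives
  per-gene seeds from the configured seed, making reruns byte-identical.

## Limitations

* The MVN(0, R) null is asymptotic; very small GWAS samples or very rare
  variants are outside its comfort zone.
* p_AT rests on the moment-matched residual approximation; it is
  validated against Monte Carlo in the range p ≥ 1e−3 and clamped to the
  min-p sandwich elsewhere. Far-tail p_AT values inherit the accuracy of
  the moment-matched thresholds.
* The DE stage is a transparent analog of count-based DE analyses, not a
  replacement for shrinkage-based tools at n = 3.
* Reference-panel mismatch (ancestry, imputation differences) biases R
  and therefore every downstream p-value; the package harmonizes alleles
  but cannot detect panel mismatch.
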