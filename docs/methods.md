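# Methods

`polyfactor` implements a cross-trait genetic analysis pipeline for
case/control GWAS summary statistics: genetic covariance estimation by
multivariate LD-score regression, latent-factor modelling of that
covariance, factor-level GWAS with a per-SNP heterogeneity test, decomposition
of associated regions into conditionally independent signals, Bayesian
colocalization of signals across factors and with molecular QTLs, and
single-instrument Mendelian randomization. This note records the models,
the parameters that matter, the numerical choices, and what the synthetic
testbed does and does not demonstrate.

## Synthetic data generator

The generator is the testbed for every stage, so its assumptions are stated
first.

**LD panel.** Haplotypes within a block follow a stationary copy chain: the
allele at position j+1 duplicates position j with probability ρ and is
otherwise drawn fresh from the block's allele frequency. The correlation
between variants at lag d is therefore exactly ρ^d, and a genotype is the
sum of two independent haplotypes with the same correlation profile. This
gives closed-form expected LD, which the LD-score and conditional-analysis
tests exploit as oracles. Blocks are mutually independent and separated by
1 Mb so that no window-based computation bridges them. All variants in a
block share one frequency drawn uniformly from (0.05, 0.95); ρ may vary by
block (the bundled study draws ρ ~ U(0.1, 0.7), which spreads LD scores
over roughly 1–6 and is what makes the LD-score regression well
identified).

**Effect sizes.** Effects are parameterised on the standardized-genotype
scale and converted to the allele-dosage scale once, when a summary table
is assembled (β = z / √(N·2f(1−f))). Under the generative model each trait
t has joint causal effects b_t = Λγ + δ_t: γ is the per-variant effect on
each latent factor, δ the per-trait direct effect that bypasses the
factors. The polygenic background draws γ_j ~ MVN(0, Φ/m) and
δ_jt ~ N(0, Θ_tt/m) for every variant, so the summed causal covariance
converges to ΛΦΛᵀ + Θ — exactly the quantity LD-score regression
estimates. The within-factor SNP-effect correlation is a free parameter
(`factor_effect_corr`) defaulting to Φ itself.

**Marginal statistics.** E[z_t] = √N_t · R b_t with R the block LD matrix;
errors are multivariate normal with covariance R across variants and, across
traits, the overlap-induced correlation c_ab = (shared-sample fraction) ×
(phenotypic correlation among shared samples). Case/control designs enter
only through the effective sample size 4v(1−v)(n_cases+n_controls) summed
over cohorts; no liability-threshold sampling is performed, because the
z-score scale under effective N is exactly what the pipeline consumes.

**QTLs.** A molecular QTL table has a single causal variant (or none) with
a chosen standardized effect; everything else is LD-propagated noise.

**What the generator does not emulate:** imputation error and variable
imputation quality, allele-frequency drift between study and reference,
non-normal phenotypes, population stratification (the LDSC intercept is
exercised only through sample overlap), interaction effects, and realistic
coalescent LD (AR(1) blocks have no long-range structure). Passing tests
therefore demonstrate correctness of the estimators under their stated
assumptions, not robustness to real-data pathologies.

## Harmonization

Munging restricts to a reference variant list, resolves allele orientation
(direct, swapped with effect negation, strand complement, or removal when
irreconcilable), drops strand-ambiguous A/T and C/G variants, removes rows
with zero effect or zero standard error, applies a MAF floor (default 1%,
study frequency preferred, reference frequency as fallback), and recomputes
p from the harmonized z so all downstream thresholds act on one scale; the
original p survives in an audit column. Munging is idempotent and never
adds rows.

## LD-score regression

LD scores sum adjusted squared correlations r² − (1−r²)/(n_ref−2) within a
physical window (default 200 kb — generous relative to the 30 kb block
span of the panel). For each trait pair,

    E[z_a z_b] = √(N_a N_b) · cov_g · ℓ_j / M + intercept,

fitted by weighted least squares in two passes: 1/ℓ weights, then the
standard heteroskedasticity weights rebuilt from first-pass estimates. M is
the panel variant count (per-SNP h² bookkeeping), not the post-filter
regression count. Variants with χ² > max(80, 0.001·N) are excluded.
Standard errors come from a delete-one-block jackknife over 200 contiguous
blocks; the sampling covariance V of all k(k+1)/2 slopes (row-major lower
triangle) is formed from the jointly resampled delete-one estimates, which
is what lets sample-overlap-induced dependence between elements propagate
into the factor-model weights. Heritabilities are observed-scale under the
effective-N convention.

## Factor model

Candidate models declare which traits load on which factors; factors have
unit variance so loadings are standardized paths, factor correlations are
free, residual variances free. Estimation minimizes the diagonally weighted
discrepancy (s − σ(θ))ᵀ diag(V)⁻¹ (s − σ(θ)) with a trust-region
least-squares solver, analytic Jacobian, and three deterministic starts
(two fixed loading levels plus a correlation-informed start); the best
convergent optimum wins. Full-V weighting sits behind a flag. Negative
residual variances are flagged as Heywood cases, never clamped. A non-PSD
input S is projected to the nearest PSD matrix (eigenvalue floor 1e-6) and
the smoothing recorded.

The model fit statistic is the residual quadratic form evaluated against
the asymptotic covariance of the residuals, r′ pinv((I−P)V(I−P)′) r, which
is χ² with df = k(k+1)/2 − #free parameters; the raw diagonally-weighted
objective is not χ²-distributed and is reported separately as `objective`.
CFI uses the standard clamped formula against an independence baseline;
SRMR standardizes observed and implied matrices by the observed standard
deviations and averages over distinct elements. Adequacy is CFI > 0.95 and
SRMR < 0.10; among adequate candidates the fewest-factor model wins, and
interpretability exclusions are declared in configuration, never inferred.
Trait groups feeding candidate models come from connected components of the
genetic-correlation graph at threshold 0.4.

## Factor GWAS and Q_SNP

Per variant, S is augmented with the SNP variance 2f(1−f) and SNP–trait
covariances β_t·2f(1−f); the sampling covariance of the latter combines
per-trait standard errors with the intercept-derived cross-trait error
correlation. Holding the measurement model and the total factor variance at
their genome-wide values makes the SNP–trait covariance vector linear in
the SNP→factor paths, c = 2f(1−f)·Λγ, so estimation is closed-form WLS
(diagonal weights, sandwich standard errors with the full covariance).

Q_SNP is the generalized-least-squares residual of the common-pathway
model: since the independent-pathways model (SNP → every trait directly)
fits the k SNP–trait covariances perfectly, the fit-statistic difference
equals cᵀ(V⁻¹ − V⁻¹A(AᵀV⁻¹A)⁻¹AᵀV⁻¹)c, which is exactly χ² with
df = #traits − #factors under the null that the variant acts only through
the factors. One omnibus statistic is computed per variant (a per-factor
decomposition would be an alternative; the omnibus form is reported with
its df). Negative values from numerical degeneracy are clamped to zero
with a warning. Factor tables carry an implied effective N of
1/(se²·2f(1−f)) so they can feed the conditional stage unchanged.

## Regions

Variants below 1e-6 are chained per chromosome; a gap strictly greater than
250 kb splits chains (boundary equality keeps one region). A region is
significant if a member reaches 5e-8. Per-GWAS significance filtering
happens before cross-GWAS merging by default (a config switch reverses the
order); merging is transitive with min/max boundary union. Regions
overlapping chr6:25–35 Mb at any base are excluded ("encompassing" read as
overlap). Region bounds are seed-variant bounds; the ±100 kb padding is
applied by the conditional stage.

## Conditional decomposition

The joint-regression sufficient statistics are rebuilt from summary data:
X′X from the reference LD correlations scaled by √(D_j D_k) with
D_j = 2f_j(1−f_j)N_j (or the in-sample genotype sum of squares when the
reference is the cohort itself, in which case all estimates coincide with
exact multiple regression — the module's central oracle, verified to 1e-6
at n = 2000, m = 200); y′y from the marginal identity, median across
variants; residual variance on n − p − 1 degrees of freedom. Forward
selection adds the smallest-conditional-p variant (ties: smaller p, then
lower position) and stops when every conditional p exceeds 1e-4 — entry
and stopping thresholds coincide. Candidates with r² > 0.9 against the
selected set are skipped, as are candidates producing singular systems;
summary-vs-reference frequency gaps above 0.2 drop the variant. Each
selected variant then gets an "all-but-one" dataset: every region variant
re-estimated conditional on the other selected variants. A signal is valid
if its dataset's minimum conditional p is below 1e-6 or that variant's
marginal p is below 5e-8. Protein QTLs skip this stage entirely and are
colocalized as a single marginal main effect.

## Colocalization and MR

Per-variant evidence is the Wakefield approximate Bayes factor
½(log(1−r) + r z²) with r = prior_sd²/(prior_sd² + se²); prior standard
deviations are 0.2 for case/control (and factor) effects and 0.15 for
quantitative molecular traits. The five-hypothesis enumeration uses priors
p1 = p2 = 1e-4, p12 = 1e-5 and log-sum-exp throughout; fewer than 25 shared
variants yields an explicit "untestable" result. Signals with PP4 ≥ 0.9
are grouped by connected components; groups spanning two or more factors
are labelled shared. Expression QTLs are decomposed before colocalization;
protein QTLs use main-effect mode. For colocalizing pairs, the Wald ratio
β_out/β_exp with first-order delta-method standard error gives the MR
estimate; the instrument is the exposure's smallest conditional-p variant
also present in the outcome dataset, and results with p < 0.05 are flagged
reportable. Positive estimates are labelled predisposing, negative
protective. No multiple-testing correction is applied to MR p-values.

## The bundled study

Nine immune-mediated traits (CD, UC, PSC / T1D, SLE, JIA, RA / AST, ECZ)
load on three factors (gut, autoimmune, allergic) with covariance-scale
loadings 0.36–0.45, factor correlations 0.25 and residual genetic variances
0.09–0.12 (total h² ≈ 0.25–0.30, typical for these diseases on the
observed scale). Effective sample sizes (≈40–60k) derive from two
case/control cohorts per trait through the effective-N formula; CD and UC
share half their samples with phenotypic correlation 0.2. The panel holds
30,000 variants (1000 blocks of 30), which puts the mean association χ²
near 1.8 — the per-SNP signal regime of well-powered real GWAS — while
keeping the full pipeline under two minutes on one CPU. Planted truth: 12
factor-specific loci, 3 two-factor and 1 three-factor shared locus, 3
heterogeneous (single-trait) loci for Q_SNP, 5 expression QTLs (3 sharing a
planted causal variant, 2 with a distinct variant in the same region) and 1
shared protein QTL in main-effect mode. Problem sizes in the test suite
(20,000-variant LDSC recovery panels, 1000-variant calibration sets,
n = 2000 × m = 200 conditional oracle) were chosen as the smallest scales
at which the statistical claims are meaningful.

## Known limitations

- The AR(1) panel cannot represent long-range LD or the MHC; the HLA
  exclusion is exercised only structurally.
- Observed-scale heritability under effective N; no liability conversion.
- The WLS fit statistic relies on the jackknife V being well estimated;
  with few blocks the χ² calibration of CFI degrades.
- Single-causal-variant colocalization inherits coloc's assumption; regions
  with multiple shared variants are handled only through prior
  decomposition.
- Wald-ratio MR uses one instrument and first-order delta SEs; no
  pleiotropy-robust estimators.
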