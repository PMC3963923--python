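# Methods

This note records the statistical models `admixfine` implements, the choices
made where the design was genuinely open, and what the synthetic-data
validation does and does not establish.

## Setting and notation

Two-way admixed individuals (African / European ancestral backgrounds).  At
marker *m*, individual *j* carries `a_jm ∈ {0,1,2}` African-origin alleles
(diploid local ancestry), genotype `g_jm ∈ {0,1,2}` copies of the coded
allele, and has global African ancestry `θ_j ∈ [0,1]`.  Case status is
`y_j ∈ {0,1}`; families define clusters; sex is a covariate throughout.
Coordinates are 1-based and region intervals closed on both ends (VCF
convention; the package's BED-like region tables document this divergence
from half-open BED).

## Local-ancestry bookkeeping (`ancestry`)

Upstream sliding-window estimators leave two gaps that are filled by rules
rather than re-estimation: markers covered by several overlapping windows
take the **majority vote** of the window calls, and markers absent from the
genotyping array take the ancestry of the **nearest genotyped marker**.
Both needed a deterministic tie-break that the rules themselves do not fix:
ties in the vote go to the smallest ancestry count, and equidistant
neighbours resolve to the lower position.  Any deterministic choice would
do; these make reruns byte-identical.  Global ancestry is the genome-wide
mean of `a_jm / 2`.

## Association (`assoc`)

Case status is modelled by logistic regression fit with generalized
estimating equations: independence working correlation, families as
clusters, cluster-robust (HC0-style) sandwich covariance without
small-sample correction (a correction flag exists but is off by default;
with singleton clusters the fit reduces exactly to the ordinary logistic
MLE with heteroskedasticity-robust errors, which the tests assert).
Genotypes enter multiplicatively (log-additive dosage).  Every model
includes `θ` and sex; local-ancestry adjustment adds `a_jm`.  The coded
allele is the cohort minor allele.  Confidence intervals are Wald,
`exp(β ± 1.96·SE)`.  Confounding by local ancestry is summarized as
`|β_adj − β_unadj| / |β_unadj|`.

Forward selection adds, at each step, the marker with the smallest
conditional p-value given all previously selected genotypes, stopping at
`p > α` (default 0.05); ties break by genomic position, and candidates in
near-perfect LD (r² ≥ 0.99) with a selected marker are skipped so duplicated
columns can never enter twice.  LD is the composite (unphased) r²: squared
Pearson correlation of dosages.

Missing genotypes drop an individual only for the marker being tested.

## Admixture scores (`admixscore`)

All four statistics are 1-df likelihood-ratio tests built from two pieces of
one likelihood, which makes the DIFF decomposition exact rather than
approximate:

* **ADM** (affected-only).  Among cases,
  `a ~ Binomial(2, λθ/(λθ + 1 − θ))`; ADM = 2[ℓ(λ̂) − ℓ(1)].  Individuals
  with θ ∈ {0,1} carry no information and are skipped.
* **SNP1** (allelic, conditional on local ancestry).  A retrospective
  haplotype likelihood: control haplotypes of African / European origin
  carry the coded allele with probability `p_A` / `p_E`; case haplotypes
  with probability `p·r / (1 + (r−1)p)` (rare-disease inflation by the
  allelic odds ratio r).  Ancestry heterozygotes are unphased; their
  genotype probability sums over the two origin assignments.  Individuals
  aggregate into (status × ancestry × genotype) cells.
* **MIX**.  Under the hypothesis that this single SNP causes the ancestry
  signal, the ancestry odds ratio is induced:
  `λ(r) = (1 + (r−1)p_A) / (1 + (r−1)p_E)`.  MIX maximizes
  `ℓ_ADM(λ(r)) + ℓ_SNP1(r)` over one free parameter.
* **DIFF = ADM + SNP1 − MIX**, the 1-df test of the constraint itself
  (two free parameters versus one); DIFF p < 0.05 indicates the region
  needs more than this SNP.

**Nuisance frequencies.**  When the caller supplies `(p_A, p_E)` they are
treated as known (plug-in); in that case SNP1 collapses exactly to the
binomial allelic LRT when `p_A = p_E`.  When they are estimated from the
sample — the normal pipeline path — plug-in is *not* valid: simulation
showed it inflates the SNP1/MIX type-I error to ≈0.15 at nominal 0.05,
because the test then ignores the sampling error of the estimated
frequencies.  The default therefore profiles `(p_A, p_E)` as nuisance
parameters: the null fit is the pooled ML frequency estimate (closed-form
EM over latent haplotype origins), the alternative maximizes over
`(log r, logit p_A, logit p_E)` by bounded quasi-Newton from three starting
values of r bracketing 1, with r confined to [1/50, 50].  A dense-grid
oracle test confirms the optimizer finds the same constrained optimum.
Reported `p̂_A, p̂_E` are the null-restricted estimates.

Because the retrospective scores assume unrelated subjects, `averaged_mix`
draws repeated subsamples of unrelated individuals (default 100 draws of
933 cases + 846 controls, the composition the pipeline standardizes on),
averages the *statistics* (not the p-values), and converts the averaged
statistic through the 1-df chi-square upper tail.

Admixture-region boundaries are the positions of the first and last marker
with affected-only p < 0.05.  The tiered screen passes to MIX testing only
markers with unadjusted association p < 0.05 and confounding ratio below a
threshold; "minimal confounding" is not quantified anywhere authoritative,
so the default 0.15 is an explicit configuration value, not a claim.

Significance tiers (5×10⁻⁸ genome-wide, 10⁻⁵ suggestive) are output labels,
never filters.

## Heritability (`vc`)

The ancestry relationship matrix treats `a_jm` exactly like a genotype
dosage: with `p̄_m` the sample mean African proportion at marker m,

    A_jk = (1/M) Σ_m (a_jm − 2p̄_m)(a_km − 2p̄_m) / (2p̄_m(1 − p̄_m)),

dropping zero-variance markers from M.  Whether the original covariance was
standardized or raw is not documented in the sources this design follows;
standardized is the default and raw covariance is available by flag.  A
genotype GRM (MAF > 1%) is provided for comparison.  Note that with
heterogeneous θ the mean diagonal exceeds 1 by `Var(θ)/(p̄(1−p̄))`; the unit
diagonal only holds for exchangeable individuals.

REML on the observed 0/1 scale maximizes the restricted likelihood of
`V = σ²_a A + σ²_e I` with intercept, θ and sex projected out, by
average-information iterations in the eigenbasis of A (one symmetric
eigendecomposition per matrix, cached): each iteration is O(nk²).
Safeguards: EM fallback when the AI step is invalid, step-halving when the
likelihood decreases, variance floor 1e-6 of the phenotypic variance,
boundary handling that pins a floored component with negative gradient, and
a stall detector for flat ridges.  Convergence is |Δlogℓ| < 1e-8.  The SE
of h²_obs comes from the delta method on the inverse AI matrix.  The LRT
against σ²_a = 0 uses the closed-form null (OLS residual variance) and a
1-df chi-square p-value; at the boundary this is conservative, which the
null-calibration test asserts as an upper bound.  `constrain=False` lifts
the non-negativity floor on σ²_a (keeping V positive definite), removing
the truncation bias that otherwise makes averages of replicate estimates
exceed a true h² of 0 — the unconstrained mode is what the recovery
experiments use.

Liability transform (prevalence K = 1/1000 by default, sample case
proportion P):  `h²_liab = h²_obs · K²(1−K)² / (z² P(1−P))`, z the standard
normal density at the threshold Φ⁻¹(1−K); capped at 1 with a warning.

Region removal rebuilds the matrix over markers outside the closed interval
and refits; subgroup fits contrast one radiographic subphenotype against
all controls with P recomputed.  Heritability inputs are pre-filtered to
the unrelated subset (relationship < 0.125).

## Relatedness (`kin`)

Pedigree kinship by the standard recursion with founders assumed outbred
(self-kinship 1/2), cycles rejected; relationship = 2φ.  Genotype kinship
by the KING-robust between-family estimator
`φ̂ = (N_het,het − 2N_opp-hom) / (N_het,i + N_het,j)` over markers typed in
both individuals — allele-frequency-free, hence usable under admixture,
though large ancestral frequency differentials still perturb it (the
validation simulates both matched and differentiated frequencies).
Unrelated-subset selection greedily removes the individual with most
relationships ≥ 0.125 (ties: larger id removed) until none remain; greedy
rather than maximum-independent-set because determinism and near-optimality
matter more here than the last few retained samples.  The retained set
provably contains no pair at or above threshold, asserted as a hard
post-condition.  Pedigree-based relationship takes precedence when a
pedigree is available; KING serves genotype-only inputs.

## QC (`gqc`)

Markers fail on call rate ≤ 0.95, MAF ≤ 0.01, stratified Hardy–Weinberg
exact p below 1e-4 (cases) / 1e-3 (controls), differential missingness
(2×2 Fisher exact) ≤ 1e-3, or a supplied imputation info score < 0.5 (the
info measure is accepted as a column, never recomputed — imputation is out
of scope).  The HWE test conditions on allele counts and sums probabilities
of heterozygote configurations no more probable than observed, computed by
the log-recurrence; an independent factorial-formula enumeration oracle
verifies it for all inputs up to 50 individuals.  Samples fail on call rate
< 0.90, heterozygosity beyond ±5 SD, or duplicate pairs (IBD > 0.25) with
the lower id retained; declared family members can be exempted from the
duplicate screen, since the cohort-wide screen would otherwise flag true
sibs.  Genotype posteriors harden at ≥ 0.9, inclusive — the common tool
behaviour where strictness is unstated.

## Synthetic cohorts (`simcohort`)

The generator reproduces the statistical structure the estimators assume,
with defaults fixed at the study conditions the package standardizes on:

| parameter | default | meaning |
|---|---|---|
| θ distribution | Beta, mean 0.82, SD 0.10 (moment-matched) | global African ancestry |
| generations since admixture | 7 | ancestry-tract switch rate |
| recombination | 10⁻⁸ per bp | bp → Morgan map |
| disease intercept | logit(1271/2727) | baseline case odds |
| subphenotypes | (0.331, 0.465, 0.204) | resolved / Stage I–III / Stage IV among cases with follow-up |
| follow-up missing | 0.268 | cases without subphenotype |
| genotype missingness | 0 | raised only to exercise QC |

Haplotype ancestry follows a two-state Markov chain with stationary
distribution (θ, 1−θ) and refresh probability `1 − exp(−g·d)` per
inter-marker gap of d Morgans — the Markov approximation of a g-generation
admixture pulse; the marginal P(African) is θ at every marker.  Alleles are
drawn per haplotype from `f_AFR` / `f_CEU` (zero frequency on one background
allowed).  Families arise from two simulated parents via Haldane meiosis,
so sibs share realistic genotype and ancestry; a child's stored θ is the
mid-parent value, its expectation.  Phenotypes follow
`logit P(case) = β₀ + Σ log r·g + γθ + δ·sex (+ per-locus ancestry
effect)`.  A separate vectorized single-marker scenario sampler performs
retrospective case-control ascertainment at low prevalence (default 0.02)
for calibration studies.

**What passing tests do not show.**  The generator has no LD within
ancestral populations (alleles independent given ancestry), no genotyping
error, exact local-ancestry calls, and a correctly specified logistic
disease model.  Calibration and recovery results therefore validate the
estimators under their own assumptions; on real data, local-ancestry error,
background LD and model misspecification will add noise and possibly bias
that these tests cannot detect.  The θ distribution shape and the
admixture-generation count are configuration knobs, not claims about any
real population.

## Numerical conventions

Scalar likelihood maximizations use a bracketing grid plus bounded Brent
(tolerance 1e-10) on log-odds-ratio scales confined to [1/50, 50]; the
three-parameter profile uses L-BFGS-B (ftol 1e-13) with multi-start.  A
grid-plus-local-refinement search was chosen over pure Newton for
robustness near boundary frequencies; a dense-grid test pins the argmax to
1e-3 on the log scale.  DIFF is clipped at 0 within 1e-6 (the constrained
optimum can numerically overshoot the unconstrained one by optimizer
noise); larger negative values raise, since they indicate non-nested
inputs.  Percentages in summaries round half-away-from-zero at one decimal,
reproducing printed-table arithmetic exactly.  All simulations accept a
single integer seed and are byte-reproducible; problem sizes in the
acceptance checks (600–2,000 replicates at n = 1,500; 30 REML replicates at
n = 2,000 with 250 markers) were chosen to keep Monte-Carlo error well
inside the asserted bands.

## Known limitations

Two-way admixture only; no mixed-model association (GEE covers familial
correlation for fixed effects but not polygenic variance in association
tests); single-component GREML (no partitioned heritability, no bivariate
genetic correlation); the duplicate/IBD sample screen is cohort-wide with a
family exemption flag rather than dataset-pair aware; X-chromosome models
and haplotype tests are absent.
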