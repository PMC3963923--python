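# admixfine

Admixture fine-mapping for two-way admixed case-control cohorts.

In recently admixed populations such as African Americans, a disease that is
more common in one ancestral population leaves a signature: cases carry an
excess of the higher-risk ancestry at loci that harbor risk variants.
Admixture mapping finds such loci; the harder question is whether a *single
candidate SNP* inside an ancestry-associated region accounts for the
ancestry signal, or whether further variants remain.  `admixfine` implements
the full analysis chain for that question, aimed at statistical geneticists
working with genotype + local-ancestry data from two-way admixed cohorts
with related individuals.

## What it computes

For individual *j* at marker *m*, let *a<sub>jm</sub>* ∈ {0,1,2} be the
number of African-origin alleles (local ancestry), *θ<sub>j</sub>* the
genome-wide African proportion (global ancestry), *g<sub>jm</sub>* the
risk-allele count, and *y<sub>j</sub>* case status.

* **Association (`assoc`)** — logistic GEE with independence working
  correlation and cluster-robust (sandwich) variance, families as clusters:
  logit P(y=1) = β₀ + β·g + γθ + δ·sex (+ local-ancestry dosage when
  adjusting).  OR = e^β with Wald 95% CI; the local-ancestry confounding
  ratio is |β_adj − β_unadj| / |β_unadj|.  Also stratified ORs by ancestry
  count, conditional ancestry tests, forward selection, and composite-LD r².
* **Admixture scores (`admixscore`)** — four nested 1-df likelihood-ratio
  statistics: **ADM**, the affected-only test of the ancestry odds ratio λ
  in a ~ Bin(2, λθ/(λθ+1−θ)); **SNP1**, the allelic odds ratio *r* in a
  retrospective haplotype likelihood conditional on local ancestry with
  ancestral frequencies (p_A, p_E) profiled; **MIX**, the same joint
  likelihood maximized along the single-causal constraint
  λ(r) = (1+(r−1)p_A)/(1+(r−1)p_E); and **DIFF = ADM + SNP1 − MIX**, the
  test of that constraint — DIFF p < 0.05 means one SNP is not enough to
  explain the ancestry signal.  Scores can be averaged over repeated random
  subsamples of unrelated subjects (default 933 cases + 846 controls).
* **Heritability (`vc`)** — single-component GREML where the relationship
  matrix is built from local-ancestry counts standardized like genotype
  dosages (or from genotypes for comparison); AI-REML with EM fallback on
  the observed 0/1 scale, then the liability-scale transform
  h²_liab = h²_obs · K²(1−K)² / (z²P(1−P)) at prevalence K = 1/1000.
  Region-removal quantifies how much heritability an admixture locus carries.
* **Relatedness (`kin`)** — recursive pedigree kinship, KING-robust
  genotype kinship, and greedy unrelated-subset selection at relationship
  < 0.125 (first cousins).
* **QC (`gqc`)** — call rate > 95%, MAF > 1%, Hardy–Weinberg exact tests
  stratified by status (P > 10⁻⁴ cases / 10⁻³ controls), differential
  missingness, heterozygosity outliers, duplicates, and 0.9-threshold
  hardening of imputed genotype posteriors.
* **Synthetic cohorts (`simcohort`)** — two-way admixed individuals with
  θ ~ Beta(mean 0.82, SD 0.10), Markov ancestry tracts (7 generations since
  admixture, 10⁻⁸ recombination/bp), ancestry-specific allele frequencies,
  sibships through simulated meiosis, a multiplicative logistic disease
  model and radiographic subphenotypes — so the whole chain is testable
  end to end with known truth.

## Worked example

```python
import numpy as np
from admixfine.simcohort import SimConfig, DiseaseModel, simulate_cohort
from admixfine.cohort import AncestralFrequencies
from admixfine.admixscore import cohort_scores
from admixfine.assoc import snp_association

cfg = SimConfig(
    n_individuals=3000, n_families=0, n_markers=1, seed=7,
    freq_table=AncestralFrequencies.constant(1, 0.09, 0.65),
    disease=DiseaseModel(intercept=-1.5, causal={0: np.log(1.5)}))
cohort = simulate_cohort(cfg)

assoc = snp_association(cohort, 0)
print(f"OR {assoc.odds_ratio:.2f} ({assoc.ci_low:.2f}-{assoc.ci_high:.2f}), "
      f"p = {assoc.p_value:.2e}")
scores = cohort_scores(cohort, 0)
print(f"ADM p {scores.adm_p:.3f}  SNP1 p {scores.snp1_p:.2e}  "
      f"MIX p {scores.mix_p:.2e}  DIFF p {scores.diff_p:.3f}")
```

prints

```
OR 1.47 (1.26-1.72), p = 7.34e-07
ADM p 0.001  SNP1 p 3.95e-05  MIX p 1.67e-07  DIFF p 0.845
```

Read: the simulated variant is risk-increasing (OR 1.47, recovering the
simulated allelic odds ratio of 1.5 within sampling error); the locus shows
a case ancestry excess (ADM p 0.001); MIX is more significant than the
allelic test alone because the allele's large ancestral frequency
differential (p_A = 0.09 vs p_E = 0.65) predicts exactly the observed
ancestry shift; and DIFF p = 0.85 says this one SNP fully accounts for the
admixture signal.

A thin CLI mirrors the library: `admixfine simulate | qc | assoc | mixscore
| h2 | kinship | summary | run` (see `admixfine --help`).

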