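# Methods

`admixprs` implements the analysis pipeline of a polygenic-risk-score
(PRS) study in an admixed Parkinson's-disease-style case-control
cohort: quality control and relatedness pruning, LD clumping and
pruning+thresholding PRS construction, case-control evaluation
statistics, age-at-onset survival analysis, population-structure
inference, and a focal-SNP haplotype analysis. Because the cohorts such
studies use are access-restricted, the package ships a synthetic
admixed-cohort generator with known ground truth; every stage is
validated by parameter recovery against that truth.

## Scoring model

The PRS of subject *i* is the weighted effect-allele dosage sum
PRS_i = Σ_j β_j d_ij, with β_j the discovery-GWAS log-odds effect.
Harmonization aligns each discovery record to the target VCF by allele
identity: when the effect allele is the VCF alt allele, d is the alt
dosage; when it is the ref allele, d = 2 − alt dosage. The weight is
never sign-flipped — the score always counts effect alleles — which
makes scoring exactly invariant to ref/alt relabeling (tested to
1e−12). Records whose alleles match neither configuration, and
strand-ambiguous (A/T, C/G) records, are removed before scoring.
Missing dosages are mean-imputed per variant by default (a `drop` mode
removes incomplete variants instead).

Clumping is the PLINK/PRSice greedy rule: visit variants by ascending
discovery p (ties by chromosome, position); each unassigned variant
becomes an index and absorbs unassigned same-chromosome variants within
the window whose dosage r² exceeds the threshold. Defaults r² = 0.1,
window 250 kb, MAF floor 5% (inclusive). Pruning+thresholding scores
the clump indices below each cutoff of a p-value grid
(5e−8 … 1) and selects the cutoff maximizing the Nagelkerke pseudo-R²
increment of `status ~ PRS + covariates` over the covariate-only model.

## Evaluation statistics

* **Logistic association.** Maximum-likelihood fit with Wald tests;
  the pseudo-R² is Nagelkerke's normalization of the likelihood-ratio
  R² computed against the covariate-only model, so it reads as the
  PRS's increment.
* **Liability-scale R².** Lee et al.'s ascertainment transform with
  population prevalence K, sample case fraction P, threshold
  t = Φ⁻¹(1−K) and ordinate z = φ(t):
  C = K²(1−K)²/(z²P(1−P)), θ = m·(P−K)/(1−K)·(m·(P−K)/(1−K)−t) with
  m = z/K, and R²_l = C·R²_o/(1 + C·θ·R²_o). The observed-scale input
  R²_o is the squared point-biserial correlation between status and
  the score (a linear-probability R², the input scale the transform
  assumes). K is a required scientific input; the default 0.005 (a
  plausible Parkinson's prevalence) is logged loudly when used.
* **ROC/AUC.** Mann–Whitney formulation with half-credit for ties;
  DeLong structural-component variance for the CI and for the paired
  two-score test. Classification metrics are reported at the Youden's
  J operating point (ties resolved toward the more specific, i.e.
  higher, threshold).
* **Quintile odds ratios.** Quintile boundaries are taken on the full
  analyzed sample (cases and controls jointly), boundary ties assigned
  to the lower quintile; logistic fit with quintile indicators
  (reference = lowest) and Wald 95% CIs.
* **Risk-allele frequency contrast.** Per variant the risk allele is
  the effect allele when β > 0, otherwise the other allele; a 1-df
  chi-square tests the lower-vs-higher split between two populations
  against 50:50.

## Relatedness

KING-robust between-family kinship:
φ̂ = (N_Aa,Aa − 2·N_AA,aa)/(N_Aa^(i) + N_Aa^(j)) over the pair's shared
non-missing hard-call sites, which gives 0.5 for duplicates, 0.25 in
expectation for parent-offspring and 0 for unrelated pairs without
using allele frequencies (hence robust to admixture). Pairs with fewer
than 100 shared sites are reported missing. The unrelated subset is
built by greedily removing the most-connected sample (ties by sample
id) until no pair exceeds the cutoff — 0.0884 (2nd degree) by default,
0.0442 (3rd degree) available in config — and the no-related-pair
property is re-verified on every run.

## Survival analysis

Cases contribute age at onset as event time (age at analysis when
onset is unrecorded); controls are censored at age at analysis — a
prevalent-cohort simplification, documented as such. Onsets ≤ 18 are
excluded. Kaplan–Meier curves are stratified by PRS quintile; Cox
fits use quintile indicators with Efron tie handling (lifelines'
default). A cases-only mode refits among the diagnosed, where selection
on the outcome attenuates hazard ratios toward 1 — the package asserts
this direction on synthetic data rather than treating it as a bug.

## Population structure

PCA standardizes each variant by mean 2f and SD √(2f(1−f)) and takes
left singular vectors; monomorphic variants are dropped. K-means on the
retained PCs (fixed seed, n_init = 10) labels clusters by descending
size for determinism. Admixture proportions are estimated per sample by
a supervised projection EM against fixed reference frequencies
(clipped to [0.001, 0.999]): with π_ij = Σ_k q_ik p_kj the binomial
log-likelihood Σ_j [d_ij log π_ij + (2−d_ij) log(1−π_ij)] is maximized
by the simplex-preserving update
q_ik ← q_ik [(d/π)P' + ((2−d)/(1−π))(1−P)']_k / (2M), which never
decreases the likelihood (asserted in tests). Unsupervised frequency
estimation is deliberately out of scope: the supervised projection is
identifiable, desk-scale, and sufficient for labeling clusters and
correlating ancestry with the PRS (Pearson) or contrasting PRS
distributions between groups (two-sided Wilcoxon rank-sum).

## Focal-SNP haplotype analysis

* **Blocks.** Pairwise |D′| with likelihood-grid confidence bounds
  (multinomial likelihood on a 201-point |D′| grid, equal-tail 90%
  interval — the Haploview convention). Pairs are strong-LD when
  CI ∈ [0.70, 0.98+], recombinant when the upper bound < 0.90, else
  uninformative; maximal runs with ≥ 95% strong informative pairs
  become blocks, chosen non-overlapping largest-first. All four
  thresholds are configurable.
* **Enumeration.** Distinct phased strings over the window counted on
  2n chromosomes; haplotypes above 1% frequency are labelled hap1,
  hap2, … by descending frequency and categorized by their focal-SNP
  allele; the rest pool into a rare bin excluded from testing.
* **Association and conditioning.** Each common haplotype's additive
  copy count enters a covariate-adjusted logistic fit; Bonferroni
  correction uses the number of haplotypes tested. Haplotypes with
  unadjusted p < 0.05 proceed to a 1-df likelihood-ratio test of
  (covariates + focal genotype + haplotype) against
  (covariates + focal genotype); a significant LRT means the haplotype
  carries risk beyond the focal allele. Perfect collinearity with the
  focal dosage is reported as undefined rather than tested.
* **Sharing.** The sharing between two haplotypes is the Jaccard
  overlap of their derived-allele site sets relative to an explicit
  ancestral haplotype, reported to the nearest percent. The
  denominator choice (derived-allele union rather than all window
  sites) is an interpretation; the all-sites variant is a one-line
  change on the same sets.
* **Network.** Pairwise Hamming distances; per distance class, every
  edge joining components that were distinct before the class is
  retained (minimum-spanning network, all ties kept), truncated at a
  connection limit. The statistical-parsimony limit is approximated as
  the largest step count j for which j mutations hit j distinct sites
  with probability ≥ 95% (∏_{i<j}(1 − i/L)); this is deliberately a
  transparent stand-in for the full parsimony-probability recursion
  and is overridable wherever it is consumed. Unsampled intermediate
  nodes are not inferred.

## The synthetic cohort

The generator's defaults are the study conditions every recovery test
runs under:

* **Populations.** K = 3 (African-, European- and Native-American-like),
  Balding–Nichols frequencies around a shared ancestral
  p ~ U(0.05, 0.95) with FST 0.15 per population; admixture
  q ~ Dirichlet(0.4, 1.0, 1.6), i.e. a Native-American-heavy Latin
  American cohort with a European minority component.
* **Genotypes.** 5,000 variants, ancestry drawn independently per
  haploid copy per variant (unlinked admixture). An optional block mode
  draws a small founder-haplotype pool per window (copied with 1%
  per-site mutation, population-specific founder weights) for LD
  realism.
* **Phenotype (liability channel).** 100 causal variants with effects
  N(0, h²/m) on standardized genotypes, h² = 0.3, environmental noise
  N(0, 1−h²), disease when liability exceeds the prevalence quantile.
  Prevalence defaults to 0.1 — a common-disease value chosen so that a
  1:1 case:control cohort of 2,000 can be ascertained from an internal
  pool of ~10⁴ simulants; the pool simulates causal-variant genotypes
  only and fills the remaining variants for ascertained subjects
  (exact under unlinked admixture). The pool also yields the
  generator-truth top-vs-bottom quintile odds ratio: quintile
  boundaries on the case/control mixture matching the design, odds
  from the liability-model case probabilities — the exact large-sample
  estimand of the fitted logistic contrast.
* **Discovery statistics.** Estimated in one population only:
  β̂_j = β_j + N(0, se²) with se = 1/√(2 p_dj (1−p_dj) n_d), Wald
  p-values, variants monomorphic in discovery omitted. n_d defaults to
  100,000 (a well-powered GWAS; noise ≈ 10% of a typical causal
  effect). At n_d = 20,000 the ancestry-dependent noise and selection
  produce the portability gradient: a full-statistics PRS loses ~0.05
  AUC from the highest to the lowest discovery-ancestry tertile.
* **Onset (hazard channel).** Diagnosis age follows a Weibull baseline
  (shape 5, scale 72 — onset mass in the 50s–70s) with log-hazard
  linear in the true-score quintile (top-vs-bottom log HR = log 2.3),
  applied to every subject and administratively censored at age at
  analysis (U(45, 85)). This is intentionally a proper censoring model,
  separate from the liability channel: it makes the Cox estimand equal
  the configured log HR, so CI coverage is a meaningful test. The two
  channels are validation devices, not a joint disease model.
* **Focal window.** 52 phased sites at rs356182-like coordinates; one
  ancestral A-haplotype everywhere; a discovery-type and a target-type
  G-haplotype at frequency 0.25 in their home populations (0.02
  elsewhere) whose derived-allele sets share 14% (16 derived sites
  each, 4 shared including the focal SNP → 4/28 ≈ 14.3%); per-site
  mutation 0.002 creates the rare tail; disease risk enters only
  through the focal allele at OR 1.3 — so the conditioning LRT is a
  designed null.

All randomness flows from `SimConfig.seed`; bundles are byte-identical
across regenerations, and the pipeline manifest records SHA-256 digests
of every output so two runs are verifiably identical.

### What the generator does not emulate

Coalescent-realistic LD and local-ancestry tracts, genotyping or
imputation error, site/batch effects correlated with ancestry,
age-structured sampling, and any coupling between the liability and
onset channels. Passing recovery tests therefore demonstrates that the
estimators are correct for their estimands under the stated models —
not that real-cohort results are unbiased, where LD differences between
discovery and target populations (absent here by design) are a major
additional force.

## Numerical choices

Logistic fits: statsmodels Newton ML, non-convergence or separation
flagged rather than silently reported. DeLong: midrank formulation;
degenerate variance (perfect separation) collapses the CI to a point
with a warning; identical paired scores give p = 1. D′ CI: 201-point
grid, frequencies at their MLEs. Quintile ties go to the lower
quintile. MAF filtering is inclusive at the boundary (with a 1e−12
guard against accumulation error). Constant dosage vectors have
undefined r² and are treated as unlinked. The EM stops at a
log-likelihood gain < 1e−6 or 1,000 iterations. Problem sizes in tests
(replicate counts, cohort sizes) match the generator defaults above;
oracle-equivalence checks run on deliberately small instances where
brute force is exact.

## Known limitations

Kinship is O(n²) dense matrix work — fine to a few thousand samples,
not biobank scale. The haplotype network omits TCS intermediate-node
inference, so long branches truncate into components at the parsimony
limit. The liability transform assumes the observed-scale R² comes
from a linear-probability model; pseudo-R² inputs would need a
different mapping. `read_vcf(region=...)` requires an indexed VCF.
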