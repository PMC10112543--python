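# admixprs

Polygenic risk scores and focal-variant haplotype analysis for admixed
case-control cohorts.

Polygenic risk scores (PRS) built from European-ancestry GWAS summary
statistics lose accuracy when applied to other populations, and the
loss varies with each subject's ancestry mix — a central problem for
admixed Latin American cohorts in Parkinson's disease genetics. This
package implements, as reusable tested components, the analysis such a
study runs end to end:

* **Scoring** — summary-statistics harmonization against target VCF
  genotypes (strand-ambiguous removal, allele alignment), greedy LD
  clumping (r² = 0.1, 250 kb), PRS = Σ_j β_j·d_ij, and PRSice-style
  pruning+thresholding model search.
* **Evaluation** — logistic association with covariates, Nagelkerke
  pseudo-R² increments, liability-scale R² (Lee et al. ascertainment
  transform), ROC/AUC with DeLong CIs and paired AUC tests,
  sensitivity/specificity at the Youden point, per-quintile odds
  ratios, risk-allele frequency contrasts between populations.
* **QC** — KING-robust pairwise kinship
  (φ̂ = (N_Aa,Aa − 2·N_AA,aa)/(N_Aa⁽ⁱ⁾ + N_Aa⁽ʲ⁾)), greedy unrelated
  subsets at the 2nd-degree cutoff 0.0884, MAF filtering.
* **Onset** — Kaplan–Meier curves and Cox proportional-hazards models
  of age at onset by PRS quintile (Efron ties), with a cases-only mode.
* **Ancestry** — genotype PCA, PC-space k-means, supervised admixture
  proportions by projection EM against reference frequencies, and
  PRS-by-ancestry correlation/Wilcoxon statistics.
* **Haplotypes** — Gabriel D′-confidence-interval blocks, phased
  haplotype enumeration around a focal risk SNP, covariate-adjusted
  haplotype association with Bonferroni correction, a conditioning
  likelihood-ratio test against the focal genotype, derived-allele
  sharing, and a TCS-style minimum-spanning haplotype network.
* **Synthetic cohorts** — a generator for K-way admixed genotypes
  (Balding–Nichols + Dirichlet), liability-threshold phenotypes with
  sparse causal effects, single-ancestry noisy discovery statistics
  (the source of portability bias), quintile-hazard onset ages, and
  phased focal-SNP windows with ancestry-specific risk backgrounds —
  so the whole pipeline is exercisable and testable without restricted
  cohort data.

The scientific model and every estimator are documented in
[docs/methods.md](docs/methods.md).

## Worked example

Simulate the default admixed cohort (2,000 subjects, 5,000 variants,
100 causal, h² = 0.3), build the genome-wide-significant PRS, and
evaluate it:

```python
import numpy as np
import admixprs as ap

cfg = ap.SimConfig(seed=7)                      # n=2000, M=5000, m=100, h2=0.3
bundle = ap.simulate_cohort(cfg)

records, _ = ap.remove_strand_ambiguous(bundle.sumstats)
stats = ap.harmonize(records, bundle.genotypes)
gws = stats.subset(stats.pvalue <= 5e-8)
clumped = ap.clump(gws, bundle.genotypes, r2=0.1, window_kb=250)
keep = set(clumped.index_variants)
prs = ap.score(bundle.genotypes,
               gws.subset(np.array([v in keep for v in gws.variant_ids])),
               standardize=True)

assoc = ap.logistic_assoc(prs, bundle.cohort, prevalence_k=0.1)
roc = ap.confusion_metrics(prs.score, bundle.cohort["status"].to_numpy())
top = ap.quintile_effects(prs, bundle.cohort)[-1]

print(f"PRS built from {prs.n_variants} clumped genome-wide-significant variants")
print(f"association p = {assoc.pvalue:.2e}, liability-scale R2 = {100*assoc.liability_r2:.1f}%")
print(f"AUC = {roc.auc:.3f} (95% CI {roc.ci_low:.3f}-{roc.ci_high:.3f}), "
      f"sens = {100*roc.sensitivity:.1f}%, spec = {100*roc.specificity:.1f}%")
print(f"top-vs-bottom quintile OR = {top.odds_ratio:.1f} "
      f"(95% CI {top.ci_low:.1f}-{top.ci_high:.1f})")
```

Output:

```
PRS built from 65 clumped genome-wide-significant variants
association p = 2.32e-88, liability-scale R2 = 30.5%
AUC = 0.798 (95% CI 0.779-0.817), sens = 71.6%, spec = 73.8%
top-vs-bottom quintile OR = 42.0 (95% CI 27.9-63.0)
```

Reading the numbers: the score discriminates cases from controls well
(AUC 0.80 — strong here because the simulated discovery is large and
the target cohort was ascertained at 1:1 from a 10% -prevalence
population), explains ~30% of liability variance after correcting for
case oversampling, and subjects in the top PRS quintile have ~42× the
odds of disease of the bottom quintile — the generator's closed-form
truth for this replicate is 42.3, which the Wald CI covers.

The same flow runs from the shell:

```bash
admixprs all --simulate --seed 7 --out run/
```

writing a Table-1-style evaluation report, per-sample scores, quintile
odds ratios, kinship, PCs, survival and haplotype tables, and a
`manifest.json` with SHA-256 digests of every output (two runs with the
same seed produce identical digests).

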