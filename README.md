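# vte-gxe

Statistical toolkit for two-population case-control studies of venous
thromboembolism (VTE) genetics: allele-frequency contrasts with
Hardy–Weinberg exact testing, genotype-level odds ratios with
complete-separation handling, weighted and unweighted genetic risk scores,
and gene–environment (G×E) interaction classification on the multiplicative
and additive scales.

It is aimed at genetic-epidemiology analysts comparing a minority or founder
population against a general-population reference — the motivating setting
is a cross-sectional survey of Roma and general-Hungarian adults genotyped
at six prothrombotic SNPs (rs121909567 *SERPINC1* — the antithrombin
Budapest 3 founder mutation, rs1799963 *F2*, rs2036914 *F11*, rs2066865
*FGG*, rs6025 *F5* Leiden, rs8176719 *ABO*), whose published count tables
ship with the package as a deterministic fixture.

## The statistics

For a SNP with risk-allele dosage *G* ∈ {0,1,2}:

* **Allele frequency & HWE.** p̂ = (n_het + 2·n_hom)/2n per population;
  cross-population contrast by Pearson χ² (1 df, no continuity correction)
  on the 2×2 allele table, Bonferroni-controlled at α/m (0.05/6 = 0.0083);
  Hardy–Weinberg equilibrium by the conditional exact test (sum of
  probabilities of heterozygote counts no more probable than observed).
* **Association.** Per-genotype OR = (a·d)/(b·c) with Woolf CI; the
  Haldane–Anscombe 0.5 correction on zero cells; age-adjusted ORs by
  maximum-likelihood logistic regression, with zero-case strata flagged as
  completely separated rather than reported as pseudo-converged estimates.
* **Risk scores.** uGRS = Σᵢ Gᵢ (coded 2−G for a protective orientation);
  wGRS = Σᵢ wᵢ·Gᵢ with wᵢ = ln ORᵢ from an external study.  Scores are
  dichotomised (default high ≥ 3 vs low 0–1) for band-stratified ORs.
* **G×E interaction.** A linear-probability regression of VTE on G, E,
  G×E (+ age), reported as standardized β = b·SD(x)/SD(y); joint-exposure
  stratum ORs OR₀₁, OR₁₀, OR₁₁ against the doubly unexposed cell;
  multiplicative verdict from the sign of OR₁₁ − OR₀₁·OR₁₀ and additive
  verdict from RERI = OR₁₁ − OR₀₁ − OR₁₀ + 1, each with a seeded bootstrap
  CI.  Skewed biomarkers can first be normalised by the two-step
  rank-based inverse-normal transform.

A synthetic-cohort generator draws Hardy–Weinberg genotypes, covariates and
a logistic outcome at the published study conditions, so every stage is
testable end-to-end without the (undeposited) individual-level data.

## Worked example

```python
from vte_gxe import make_study_fixture, frequency_report, genotype_or_table

cohort = make_study_fixture()          # 801 subjects, published counts
print(frequency_report(cohort)[["snp_id", "general_freq", "roma_freq", "allelic_p"]])

fgg = genotype_or_table(cohort, "rs2066865", "roma")
aa = fgg.rows[2]
print(aa.genotype_label, aa.cases, aa.noncases, round(aa.crude.estimate, 2))
```

prints

```
        snp_id  general_freq  roma_freq  allelic_p
0  rs121909567        0.0000     0.0139    0.00074
1    rs1799963        0.0197     0.0076    0.03700
2    rs2036914        0.5406     0.5063    0.17000
3    rs2066865        0.2340     0.2759    0.05400
4       rs6025        0.0690     0.0861    0.20000
5    rs8176719        0.4680     0.4823    0.57000
A/A 3 26 4.64
```

— the founder allele is carried by 1.4% of Roma chromosomes and none in the
general sample (the only contrast surviving Bonferroni control), and Roma
homozygotes for the FGG risk allele show 4.64-fold VTE odds versus
non-carriers (crude cross-product from the 3/26 vs 5/201 case/non-case
cells).

The `examples/` directory has one short script per capability
(frequencies, association, risk scores, interaction, simulation); the
`vte-gxe` console command exposes the same pipeline
(`simulate | describe | popgen | assoc | grs | gxe | run-all`) for shell
use, writing TSV reports plus a reproducibility manifest.

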