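"""Allele-frequency contrast between the two populations.

Builds the bundled count fixture (a deterministic cohort reproducing the
published genotype-by-outcome tables) and prints, per SNP: risk-allele
frequency in each population, the Hardy-Weinberg exact p, the allelic
chi-square p, and whether the difference survives Bonferroni control at
0.05/6 = 0.0083.  The founder mutation (rs121909567, SERPINC1) is present
only in the Roma stratum and is the one Bonferroni-significant contrast.
"""

from vte_gxe import frequency_report, make_study_fixture

cohort = make_study_fixture()
report = frequency_report(cohort)
print(report.to_string(index=False))
print("\nBonferroni-significant SNPs:",
      ", ".join(report[report.significant_after_bonferroni].snp_id) or "none")
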