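"""Genotype-level case-control odds ratios with separation handling.

For the FGG SNP in the Roma stratum: homozygous risk-allele carriers versus
non-carriers give a crude cross-product OR of 4.64.  The founder-mutation
heterozygote row has zero VTE cases — a completely separated stratum, which
is flagged rather than reported as a pseudo-converged estimate.
"""

from vte_gxe import genotype_or_table, make_study_fixture

cohort = make_study_fixture()

for snp_id in ("rs2066865", "rs121909567"):
    result = genotype_or_table(cohort, snp_id, "roma", compat_raw_diverged=True)
    print(f"\n{snp_id} (Roma)")
    for row in result.rows:
        if row.crude is None:
            print(f"  {row.genotype_label:>7}: {row.cases}/{row.noncases}  OR 1.00 (reference)")
        else:
            flag = "  [separated]" if row.separation_flag else ""
            print(f"  {row.genotype_label:>7}: {row.cases}/{row.noncases}  "
                  f"OR {row.crude.estimate:.2f} "
                  f"({row.crude.ci_low:.2f}, {row.crude.ci_high:.2f}){flag}")
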