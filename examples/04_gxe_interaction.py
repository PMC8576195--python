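"""Gene-environment interaction on the multiplicative and additive scales.

Simulates a cohort with a planted FGG x high-LDL interaction (log-odds 1.0
on the product term), then runs the full analysis for that pair: the
standardized linear-probability interaction coefficient, the four-stratum
odds ratios OR00/OR01/OR10/OR11, RERI, both scale verdicts, and a seeded
bootstrap CI for the interaction contrasts.
"""

from vte_gxe import GeneratorSpec, interaction_analysis, generate_cohort

spec = GeneratorSpec()
spec.n = {"roma": 20_000}
spec = spec.with_effects(
    snp_effects={"rs2066865": 0.2},
    env_effects={"ldl_c": 0.3},
    interactions={("rs2066865", "ldl_c"): 1.0},
)
cohort = generate_cohort(spec, seed=7)

r = interaction_analysis(cohort, "rs2066865", "ldl_c", population="roma",
                         bootstrap=500, seed=7)
s = r.stratum_ors
print(f"standardized beta (GxE): {r.beta_std:.3f}   p = {r.p_interaction:.2e}")
print(f"OR01 (genetic only) {s.or01:.2f}  OR10 (environment only) {s.or10:.2f}  "
      f"OR11 (both) {s.or11:.2f}")
print(f"RERI = OR11 - OR01 - OR10 + 1 = {r.verdict.reri:.2f}")
print(f"multiplicative verdict: {r.verdict.multiplicative}   "
      f"additive verdict: {r.verdict.additive}")
print(f"bootstrap 95% CI, OR11 - OR01*OR10: "
      f"({r.bootstrap.mult_excess_ci[0]:.2f}, {r.bootstrap.mult_excess_ci[1]:.2f})")
print("\nA positive planted product term shows up as synergy on both scales;")
print("point verdicts without the CI are noise-dominated at survey sample sizes.")
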