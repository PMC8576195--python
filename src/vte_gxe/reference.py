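"""Bundled reference tabulations from the motivating two-population VTE study.

The study compared 406 general-Hungarian and 395 Roma adults (ages 20-64)
genotyped at six prothrombotic SNPs, with self-reported venous
thromboembolism (VTE) as the outcome.  Only aggregate tables were published;
the constants below transcribe them so that count-level analyses and the
synthetic-cohort generator can be exercised without individual-level data.

All genotype counts are keyed by risk-allele dosage (0/1/2) and stored as
``(vte_cases, non_cases)`` pairs.  The rs8176719 indel is modelled with
abstract alleles ``C``/``DEL``; the deletion-bearing genotypes carry the
published risk-allele frequency (0.47/0.48), which is the only reading
consistent with the genotype counts.
"""

from __future__ import annotations

import math

POPULATIONS = ("general", "roma")

#: snp_id -> (gene, (non-risk allele, risk allele), placeholder log-odds weight)
#: Weights are editable placeholders on the log-odds scale for the weighted
#: risk score; the external discovery estimates were not published, so these
#: are plausible magnitudes only and never used as ground truth in tests.
SNP_PANEL = {
    "rs121909567": ("SERPINC1", ("G", "A"), None),
    "rs1799963": ("F2", ("G", "A"), 0.64),
    "rs2036914": ("F11", ("T", "C"), 0.18),
    "rs2066865": ("FGG", ("G", "A"), 0.26),
    "rs6025": ("F5", ("C", "T"), 0.88),
    "rs8176719": ("ABO", ("C", "DEL"), 0.53),
}

#: Published genotype x VTE counts: snp -> population -> dosage -> (cases, non-cases).
#: Dosages absent from a stratum (e.g. the founder homozygote) are omitted.
GENOTYPE_VTE_COUNTS = {
    "rs121909567": {
        "general": {0: (6, 400)},
        "roma": {0: (12, 372), 1: (0, 11)},
    },
    "rs1799963": {
        "general": {0: (6, 384), 1: (0, 16)},
        "roma": {0: (12, 377), 1: (0, 6)},
    },
    "rs2036914": {
        "general": {0: (1, 83), 1: (4, 201), 2: (1, 116)},
        "roma": {0: (3, 97), 1: (6, 184), 2: (3, 102)},
    },
    "rs2066865": {
        "general": {0: (2, 233), 1: (3, 149), 2: (1, 18)},
        "roma": {0: (5, 201), 1: (4, 156), 2: (3, 26)},
    },
    "rs6025": {
        "general": {0: (4, 347), 1: (2, 52), 2: (0, 1)},
        "roma": {0: (8, 323), 1: (4, 56), 2: (0, 4)},
    },
    "rs8176719": {
        "general": {0: (5, 114), 1: (1, 193), 2: (0, 93)},
        "roma": {0: (5, 101), 1: (5, 192), 2: (2, 90)},
    },
}

#: Published VTE x sex counts: population -> sex -> (cases, non-cases).
VTE_SEX_COUNTS = {
    "general": {"male": (4, 177), "female": (2, 223)},
    "roma": {"male": (4, 99), "female": (8, 284)},
}

POPULATION_N = {"general": 406, "roma": 395}

#: Published risk-allele frequencies (proportions) per population.
RISK_ALLELE_FREQ = {
    "rs121909567": {"general": 0.00, "roma": 0.01},
    "rs1799963": {"general": 0.02, "roma": 0.01},
    "rs2036914": {"general": 0.54, "roma": 0.51},
    "rs2066865": {"general": 0.23, "roma": 0.28},
    "rs6025": {"general": 0.07, "roma": 0.09},
    "rs8176719": {"general": 0.47, "roma": 0.48},
}

#: Published covariate summaries: covariate -> population -> (mean, ci_lo, ci_hi).
#: Units: age years, BMI kg/m^2, WC cm, lipids and glucose mmol/L.
COVARIATE_SUMMARY = {
    "age": {"general": (44.3, 43.1, 45.5), "roma": (43.5, 42.2, 44.7)},
    "bmi": {"general": (27.2, 26.7, 27.7), "roma": (27.5, 26.8, 28.2)},
    "wc": {"general": (96.0, 94.5, 97.5), "roma": (95.0, 93.3, 96.7)},
    "tc": {"general": (5.0, 4.9, 5.1), "roma": (4.9, 4.8, 5.0)},
    "ldl_c": {"general": (3.1, 3.0, 3.2), "roma": (3.1, 3.0, 3.2)},
    "hdl_c": {"general": (1.4, 1.3, 1.4), "roma": (1.3, 1.2, 1.3)},
    "tg": {"general": (1.6, 1.5, 1.7), "roma": (1.7, 1.6, 1.9)},
    "fbg": {"general": (5.3, 5.1, 5.5), "roma": (5.2, 5.0, 5.4)},
}

FEMALE_FRACTION = {"general": 0.554, "roma": 0.739}

CONDITION_FLAGS = (
    "cancer",
    "dm",
    "cad",
    "ckd",
    "migraine",
    "depression",
    "current_smoker",
    "quit_lt1y",
    "quit_ge1y",
    "obesity",
)

QUANTITATIVE_COVARIATES = tuple(COVARIATE_SUMMARY)


def covariate_sd(covariate: str, population: str) -> float:
    """Back out the sample SD from a published mean and 95% CI.

    The CI is mean +/- 1.96 * SD / sqrt(N); printed bounds are rounded to one
    decimal, so the recovered SD is approximate.
    """
    mean, lo, hi = COVARIATE_SUMMARY[covariate][population]
    half = (hi - lo) / 2.0
    return half * math.sqrt(POPULATION_N[population]) / 1.96
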