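"""Allele-frequency estimation, Hardy-Weinberg exact tests, and allelic association.

The allelic test contrasts risk-allele counts between the two study
populations on a 2x2 table (Pearson chi-square, 1 df, no continuity
correction), with a two-sided Fisher exact test reported alongside whenever
any expected cell is small.  Hardy-Weinberg equilibrium is assessed with the
conditional exact test: holding the allele counts fixed, the p-value sums
the probabilities of all heterozygote counts no more probable than the one
observed.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import lgamma, log

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CohortTable, SnpDef
from .errors import DegenerateDataError

DEFAULT_ALPHA = 0.05
DEFAULT_N_TESTS = 6


@dataclass(frozen=True)
class AlleleCountSummary:
    """Genotype counts and the derived risk-allele frequency for one stratum."""

    snp_id: str
    population: str
    n_hom_nonrisk: int
    n_het: int
    n_hom_risk: int

    @property
    def n_typed(self) -> int:
        return self.n_hom_nonrisk + self.n_het + self.n_hom_risk

    @property
    def n_risk_alleles(self) -> int:
        return self.n_het + 2 * self.n_hom_risk

    @property
    def risk_allele_freq(self) -> float:
        return self.n_risk_alleles / (2 * self.n_typed)


@dataclass(frozen=True)
class FreqComparison:
    snp_id: str
    freq_pop1: float
    freq_pop2: float
    chi2: float
    p_value: float
    exact_p: float | None
    significant_after_bonferroni: bool
    alpha_adjusted: float


def allele_counts(cohort: CohortTable, snp: SnpDef | str, population: str) -> AlleleCountSummary:
    """Tabulate genotype counts over typed subjects in one population stratum.

    Missing genotypes are excluded pairwise (this SNP only).
    """
    snp_id = snp.snp_id if isinstance(snp, SnpDef) else snp
    dosages = cohort.stratum(population)[snp_id].dropna().to_numpy(dtype=float)
    if dosages.size == 0:
        raise DegenerateDataError(f"no typed subjects for {snp_id} in {population!r}")
    return AlleleCountSummary(
        snp_id=snp_id,
        population=population,
        n_hom_nonrisk=int((dosages == 0).sum()),
        n_het=int((dosages == 1).sum()),
        n_hom_risk=int((dosages == 2).sum()),
    )


def counts_from_cells(snp_id: str, population: str, cells: dict[int, tuple[int, int]]
                      ) -> AlleleCountSummary:
    """Build a summary from per-dosage (cases, non-cases) count cells."""
    totals = {d: sum(cells.get(d, (0, 0))) for d in (0, 1, 2)}
    return AlleleCountSummary(snp_id, population, totals[0], totals[1], totals[2])


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test


def hwe_exact_test(counts: AlleleCountSummary) -> float:
    """Two-sided conditional exact test of Hardy-Weinberg proportions.

    Conditions on the observed allele counts; the p-value is the total
    probability of heterozygote counts whose conditional probability does
    not exceed that of the observed count.  A monomorphic stratum has a
    single attainable configuration, so p = 1 by convention.
    """
    n = counts.n_typed
    if n < 1:
        raise DegenerateDataError("HWE test requires at least one typed subject")
    n_a = min(counts.n_risk_alleles, 2 * n - counts.n_risk_alleles)  # minor allele count
    if n_a == 0:
        return 1.0
    probs = _het_count_distribution(n, n_a)
    obs = counts.n_het
    p_obs = probs.get(obs, 0.0)
    total = sum(p for p in probs.values() if p <= p_obs * (1.0 + 1e-12))
    return min(1.0, total)


def _het_count_distribution(n: int, n_a: int) -> dict[int, float]:
    """Conditional distribution of heterozygote count given allele totals.

    P(h | n, n_a) = n! * n_a! * (2n-n_a)! * 2^h
                    / [ (2n)! * ((n_a-h)/2)! * h! * (n-(n_a+h)/2)! ]
    over h with the parity of n_a, 0 <= h <= min(n_a, 2n-n_a).
    """
    n_b = 2 * n - n_a
    log_const = lgamma(n + 1) + lgamma(n_a + 1) + lgamma(n_b + 1) - lgamma(2 * n + 1)
    out: dict[int, float] = {}
    for h in range(n_a % 2, min(n_a, n_b) + 1, 2):
        hom_a = (n_a - h) // 2
        hom_b = n - hom_a - h
        logp = (log_const + h * log(2.0)
                - lgamma(hom_a + 1) - lgamma(h + 1) - lgamma(hom_b + 1))
        out[h] = float(np.exp(logp))
    return out


# ---------------------------------------------------------------------------
# allelic association between populations


def allelic_chi2_test(c1: AlleleCountSummary, c2: AlleleCountSummary,
                      alpha: float = DEFAULT_ALPHA, n_tests: int = DEFAULT_N_TESTS
                      ) -> FreqComparison:
    """Pearson chi-square (1 df) on the 2x2 risk/non-risk x population allele table.

    No continuity correction.  When any expected cell is below 5 a two-sided
    Fisher exact p is computed as well; when the allele is fixed in both
    strata the comparison is degenerate and p = 1.
    """
    if c1.snp_id != c2.snp_id:
        raise ValueError(f"mismatched SNPs: {c1.snp_id} vs {c2.snp_id}")
    table = np.array([
        [c1.n_risk_alleles, 2 * c1.n_typed - c1.n_risk_alleles],
        [c2.n_risk_alleles, 2 * c2.n_typed - c2.n_risk_alleles],
    ], dtype=float)
    alpha_adj = bonferroni(alpha, n_tests)
    if table[:, 0].sum() == 0 or table[:, 1].sum() == 0:
        return FreqComparison(c1.snp_id, c1.risk_allele_freq, c2.risk_allele_freq,
                              0.0, 1.0, None, False, alpha_adj)
    res = stats.chi2_contingency(table, correction=False)
    chi2, p = float(res.statistic), float(res.pvalue)
    expected = res.expected_freq
    exact_p = None
    if (expected < 5).any():
        exact_p = float(stats.fisher_exact(table.astype(int), alternative="two-sided")[1])
    decided_p = exact_p if exact_p is not None else p
    return FreqComparison(
        snp_id=c1.snp_id,
        freq_pop1=c1.risk_allele_freq,
        freq_pop2=c2.risk_allele_freq,
        chi2=chi2,
        p_value=p,
        exact_p=exact_p,
        significant_after_bonferroni=decided_p < alpha_adj,
        alpha_adjusted=alpha_adj,
    )


def bonferroni(alpha: float, m: int) -> float:
    """Bonferroni-adjusted per-test significance level alpha/m."""
    if m < 1:
        raise ValueError("number of tests must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    return alpha / m


def round_p(p: float) -> float:
    """Report-style rounding: two significant figures (full precision is
    retained everywhere else)."""
    if p <= 0:
        return 0.0
    from math import floor, log10
    digits = 1 - int(floor(log10(abs(p))))
    return round(p, digits)


def frequency_report(cohort: CohortTable, alpha: float = DEFAULT_ALPHA) -> pd.DataFrame:
    """One row per SNP: per-population counts/frequencies, HWE p, allelic p,
    and the Bonferroni verdict at alpha / (number of SNPs)."""
    rows = []
    m = len(cohort.panel)
    for snp in cohort.panel:
        per_pop = {}
        for pop in ("general", "roma"):
            c = allele_counts(cohort, snp, pop)
            per_pop[pop] = c
        cmp_ = allelic_chi2_test(per_pop["general"], per_pop["roma"], alpha=alpha, n_tests=m)
        row = {"snp_id": snp.snp_id, "gene": snp.gene, "risk_allele": snp.risk_allele}
        for pop, c in per_pop.items():
            row[f"{pop}_counts"] = f"{c.n_hom_nonrisk}/{c.n_het}/{c.n_hom_risk}"
            row[f"{pop}_freq"] = round(c.risk_allele_freq, 4)
            row[f"{pop}_hwe_p"] = round_p(hwe_exact_test(c))
        row["chi2"] = round(cmp_.chi2, 4)
        row["allelic_p"] = round_p(cmp_.p_value)
        row["exact_p"] = None if cmp_.exact_p is None else round_p(cmp_.exact_p)
        row["significant_after_bonferroni"] = cmp_.significant_after_bonferroni
        row["alpha_adjusted"] = round(cmp_.alpha_adjusted, 4)
        rows.append(row)
    return pd.DataFrame(rows)
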