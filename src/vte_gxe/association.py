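"""Genotype-level case-control association: contingency ORs, logistic fits,
and complete-separation handling.

Crude odds ratios come from the 2x2 cross-product with a Woolf (log-scale
Wald) confidence interval; when any cell is zero the Haldane-Anscombe
correction (add 0.5 to every cell) is applied and flagged.  Age-adjusted
estimates come from a maximum-likelihood logistic fit.  Genotype rows with
zero cases are *completely separated*: the unpenalised ML estimate diverges,
so the result carries a separation flag and the corrected crude OR instead
of a pseudo-converged number (a compatibility option exposes the raw
diverged estimate for display parity with legacy software output).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cohort import CohortTable, SnpDef
from .errors import DegenerateDataError

SEPARATION_BOUND = 15.0  # |log-odds| beyond this is treated as divergence
Z95 = 1.959963984540054


@dataclass(frozen=True)
class OddsRatio:
    """A 2x2 odds ratio with Woolf CI and correction bookkeeping."""

    estimate: float
    ci_low: float
    ci_high: float
    p_value: float
    haldane_corrected: bool

    def __iter__(self):
        return iter((self.estimate, self.ci_low, self.ci_high))


def crude_or(exposed_cases: int, exposed_noncases: int,
             unexposed_cases: int, unexposed_noncases: int) -> OddsRatio:
    """Cross-product odds ratio with Woolf CI; Haldane 0.5 on any zero cell."""
    cells = np.array([exposed_cases, exposed_noncases,
                      unexposed_cases, unexposed_noncases], dtype=float)
    corrected = bool((cells == 0).any())
    if corrected:
        cells = cells + 0.5
    a, b, c, d = cells
    log_or = np.log(a * d / (b * c))
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    from scipy.stats import norm
    z = log_or / se
    return OddsRatio(
        estimate=float(np.exp(log_or)),
        ci_low=float(np.exp(log_or - Z95 * se)),
        ci_high=float(np.exp(log_or + Z95 * se)),
        p_value=float(2 * norm.sf(abs(z))),
        haldane_corrected=corrected,
    )


# ---------------------------------------------------------------------------
# logistic regression


@dataclass
class LogisticFit:
    """Maximum-likelihood logistic fit with separation diagnostics."""

    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    converged: bool
    separation: bool
    dropped_columns: list[str] = field(default_factory=list)
    n_obs: int = 0

    def odds_ratio(self, term: str) -> OddsRatio:
        b, se = float(self.params[term]), float(self.bse[term])
        return OddsRatio(
            estimate=float(np.exp(b)),
            ci_low=float(np.exp(b - Z95 * se)),
            ci_high=float(np.exp(b + Z95 * se)),
            p_value=float(self.pvalues[term]),
            haldane_corrected=False,
        )


def fit_logistic(design: pd.DataFrame, outcome, add_constant: bool = True,
                 separation_bound: float = SEPARATION_BOUND) -> LogisticFit:
    """IRLS maximum-likelihood logistic regression with separation detection.

    Constant predictor columns are dropped (and reported); a fit whose
    coefficients run beyond ``separation_bound`` on the log-odds scale is
    flagged as separated rather than treated as converged.  A degenerate
    outcome (all cases or all non-cases) is reported as separation without
    attempting a fit.
    """
    y = np.asarray(outcome, dtype=float)
    X = design.copy()
    dropped = [c for c in X.columns if X[c].nunique() <= 1]
    X = X.drop(columns=dropped)
    if add_constant:
        X = sm.add_constant(X, has_constant="add")
    if y.min() == y.max():
        zeros = pd.Series(0.0, index=X.columns)
        return LogisticFit(zeros, zeros, pd.Series(1.0, index=X.columns),
                           converged=False, separation=True,
                           dropped_columns=dropped, n_obs=len(y))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GLM(y, X, family=sm.families.Binomial())
        res = model.fit(maxiter=200)
    slope_cols = [c for c in X.columns if c != "const"]
    separation = bool((res.params[slope_cols].abs() > separation_bound).any())
    return LogisticFit(
        params=res.params, bse=res.bse, pvalues=res.pvalues,
        converged=bool(res.converged) and not separation,
        separation=separation, dropped_columns=dropped, n_obs=len(y),
    )


# ---------------------------------------------------------------------------
# genotype-level association tables


@dataclass
class GenotypeRow:
    genotype_label: str
    dosage: int
    cases: int
    noncases: int
    crude: OddsRatio | None          # None for the reference row
    adjusted: OddsRatio | None       # age-adjusted, when requested
    raw_diverged_or: float | None    # legacy-style sentinel for separated rows
    separation_flag: bool


@dataclass
class AssociationResult:
    snp_id: str
    population: str
    reference_dosage: int
    rows: list[GenotypeRow]
    adjusted: bool
    notes: list[str] = field(default_factory=list)

    @property
    def separation_flag(self) -> bool:
        return any(r.separation_flag for r in self.rows)


def genotype_or_table(cohort: CohortTable, snp: SnpDef | str, population: str,
                      adjust_age: bool = False,
                      compat_raw_diverged: bool = False) -> AssociationResult:
    """Per-genotype case-control ORs versus the non-risk homozygote.

    Each genotype present in the stratum is compared with the reference
    (dosage 0) by the crude cross-product OR; with ``adjust_age`` an
    age-adjusted logistic OR is fitted per genotype indicator.  Zero-case
    genotypes are flagged as separated; ``compat_raw_diverged`` additionally
    reports the diverged ML point estimate those fits produce in legacy
    statistical packages.
    """
    snp_def = cohort.snp(snp) if isinstance(snp, str) else snp
    df = cohort.stratum(population)
    df = df[df[snp_def.snp_id].notna()]
    if df.empty:
        raise DegenerateDataError(f"no typed subjects for {snp_def.snp_id} in {population!r}")
    dosages = df[snp_def.snp_id].to_numpy(dtype=float).astype(int)
    vte = df["vte"].to_numpy(dtype=bool)
    counts = {d: (int(vte[dosages == d].sum()), int((~vte[dosages == d]).sum()))
              for d in sorted(set(dosages))}
    if 0 not in counts:
        raise DegenerateDataError(
            f"reference genotype absent for {snp_def.snp_id} in {population!r}")
    ref_cases, ref_non = counts[0]
    notes = []
    labels = {
        0: f"{snp_def.other_allele}/{snp_def.other_allele}",
        1: f"{snp_def.other_allele}/{snp_def.risk_allele}",
        2: f"{snp_def.risk_allele}/{snp_def.risk_allele}",
    }
    for d in (1, 2):
        if d not in counts:
            notes.append(f"genotype {labels[d]} absent from stratum; row omitted")

    adj_fit = None
    if adjust_age:
        X = pd.DataFrame({"age": df["age"].to_numpy(dtype=float)})
        for d in (1, 2):
            if d in counts:
                X[f"dosage_{d}"] = (dosages == d).astype(float)
        adj_fit = fit_logistic(X, vte)

    rows = [GenotypeRow(labels[0], 0, ref_cases, ref_non, None, None, None, False)]
    for d in (1, 2):
        if d not in counts:
            continue
        cases, non = counts[d]
        crude = crude_or(cases, non, ref_cases, ref_non)
        separated = cases == 0 or non == 0 or ref_cases == 0 or ref_non == 0
        adjusted = None
        if adj_fit is not None and f"dosage_{d}" in adj_fit.params.index and not separated:
            adjusted = adj_fit.odds_ratio(f"dosage_{d}")
        raw = None
        if separated and compat_raw_diverged:
            # the diverged ML path runs the OR to ~0 (zero cases) or ~inf
            raw = 0.0 if cases == 0 else np.inf
        rows.append(GenotypeRow(labels[d], d, cases, non, crude, adjusted, raw, separated))
    return AssociationResult(snp_def.snp_id, population, 0, rows, adjust_age, notes)


def association_report(cohort: CohortTable, adjust_age: bool = True) -> pd.DataFrame:
    """Genotype-association table across all SNPs and both populations."""
    records = []
    for pop in ("general", "roma"):
        for snp in cohort.panel:
            try:
                result = genotype_or_table(cohort, snp, pop, adjust_age=adjust_age)
            except DegenerateDataError:
                continue
            for row in result.rows:
                rec = {
                    "population": pop, "snp_id": snp.snp_id, "gene": snp.gene,
                    "genotype": row.genotype_label, "cases": row.cases,
                    "noncases": row.noncases, "separation": row.separation_flag,
                }
                if row.crude is not None:
                    rec.update(crude_or=round(row.crude.estimate, 4),
                               crude_ci=f"({row.crude.ci_low:.2f}, {row.crude.ci_high:.2f})")
                if row.adjusted is not None:
                    rec.update(adj_or=round(row.adjusted.estimate, 4),
                               adj_ci=f"({row.adjusted.ci_low:.2f}, {row.adjusted.ci_high:.2f})")
                records.append(rec)
    return pd.DataFrame(records)
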