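"""Gene-environment interaction machinery.

Four pieces:

* :func:`templeton_transform` — the two-step rank-based inverse-normal
  transformation used to normalise skewed biomarkers before regression.
* :func:`build_interaction_design` / :func:`fit_gxe_linear` — a
  linear-probability regression of the binary outcome on G, E, and G*E,
  reported as standardized coefficients (beta * SD(x)/SD(y)).
* :func:`stratum_ors` — odds ratios for the four joint-exposure strata
  OR00 (reference), OR01 (genetic only), OR10 (environment only), OR11
  (both), from cross-products against the doubly-unexposed cell.
* :func:`classify_interaction` — scale-specific verdicts: multiplicative
  synergy/antagonism from the sign of OR11 - OR01*OR10, additive from the
  relative excess risk due to interaction RERI = OR11 - OR01 - OR10 + 1.

Point verdicts at epidemiological sample sizes are noise-dominated, so a
seeded bootstrap percentile CI for both contrasts is provided alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CohortTable, SnpDef
from .errors import DegenerateDataError, ValidationError

#: Dichotomisation cut-offs for continuous exposures (mmol/L except BMI kg/m^2).
#: Direction is the *at-risk* side.
EXPOSURE_CUTS: dict[str, tuple[str, float]] = {
    "tc": (">=", 5.2),
    "ldl_c": (">=", 3.4),
    "hdl_c": ("<", 1.3),
    "tg": (">=", 1.7),
    "bmi": (">", 30.0),
}


# ---------------------------------------------------------------------------
# two-step rank-based inverse-normal transformation


def templeton_transform(values) -> np.ndarray:
    """Two-step normalisation: fractional rank -> percentile -> inverse-normal
    quantile, rescaled to the input's mean and SD.

    Step 1 assigns each value its fractional rank (ties averaged) mapped to
    the open interval (0, 1) via (rank - 0.5)/n.  Step 2 takes the standard
    normal quantile of that percentile and linearly rescales the result so
    the output's sample mean and SD equal the input's exactly.  Rank order
    is preserved; a constant vector has no defined transform.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a 1-D vector")
    if np.unique(x).size < 2:
        raise DegenerateDataError("transform undefined for a constant vector")
    n = x.size
    ranks = stats.rankdata(x, method="average")
    percentiles = (ranks - 0.5) / n
    z = stats.norm.ppf(percentiles)
    z = (z - z.mean()) / z.std(ddof=1)
    return x.mean() + x.std(ddof=1) * z


# ---------------------------------------------------------------------------
# design construction and the linear-probability interaction fit


def binarize_exposure(df: pd.DataFrame, exposure: str) -> np.ndarray:
    """Exposure as 0/1: condition flags pass through, continuous biomarkers
    are cut at their configured clinical thresholds."""
    if exposure in EXPOSURE_CUTS:
        op, cut = EXPOSURE_CUTS[exposure]
        vals = df[exposure].to_numpy(dtype=float)
        return {
            ">=": vals >= cut,
            ">": vals > cut,
            "<": vals < cut,
            "<=": vals <= cut,
        }[op].astype(float)
    return df[exposure].astype(bool).to_numpy().astype(float)


def code_genetic(dosage: np.ndarray, coding: str) -> np.ndarray:
    if coding == "dosage":
        return dosage.astype(float)
    if coding == "dominant":
        return (dosage >= 1).astype(float)
    if coding == "recessive":
        return (dosage >= 2).astype(float)
    raise ValueError(f"unknown genetic coding {coding!r}")


@dataclass
class InteractionDesign:
    X: pd.DataFrame            # columns: G, E, GxE, covariates
    y: np.ndarray              # 0/1 outcome
    dropped_columns: list[str]
    snp_id: str
    exposure: str


def build_interaction_design(cohort: CohortTable, snp: SnpDef | str, exposure: str,
                             covariates: tuple[str, ...] = ("age",),
                             genetic_coding: str = "dosage",
                             include_population: bool = False,
                             population: str | None = None) -> InteractionDesign:
    """Predictor table with G, E, their product, and covariates.

    Subjects missing the genotype or the exposure are excluded per-analysis.
    Constant columns are dropped and reported; an exposure with a single
    level after dichotomisation is an error.
    """
    snp_def = cohort.snp(snp) if isinstance(snp, str) else snp
    df = cohort.data if population is None else cohort.stratum(population)
    keep = df[snp_def.snp_id].notna()
    if exposure in df.columns:
        keep &= df[exposure].notna()
    else:
        raise ValidationError(f"unknown exposure {exposure!r}")
    df = df[keep]
    G = code_genetic(df[snp_def.snp_id].to_numpy(dtype=float), genetic_coding)
    E = binarize_exposure(df, exposure)
    if np.unique(E).size < 2:
        raise DegenerateDataError(f"exposure {exposure!r} has a single level")
    X = pd.DataFrame({"G": G, "E": E, "GxE": G * E}, index=df.index)
    for cov in covariates:
        X[cov] = df[cov].to_numpy(dtype=float)
    if include_population:
        X["roma"] = (df["population"] == "roma").astype(float).to_numpy()
    dropped = [c for c in X.columns if X[c].nunique() <= 1]
    X = X.drop(columns=dropped)
    return InteractionDesign(X, df["vte"].astype(float).to_numpy(), dropped,
                             snp_def.snp_id, exposure)


@dataclass
class LinearGxeFit:
    beta: pd.Series
    beta_std: pd.Series
    se: pd.Series
    pvalues: pd.Series
    n_obs: int
    r_squared: float
    fitted: np.ndarray

    @property
    def p_interaction(self) -> float:
        return float(self.pvalues["GxE"])

    @property
    def beta_std_interaction(self) -> float:
        return float(self.beta_std["GxE"])


def fit_gxe_linear(design: InteractionDesign | pd.DataFrame, outcome=None,
                   robust: bool = False) -> LinearGxeFit:
    """OLS of the 0/1 outcome on the interaction design (linear-probability
    model), with standardized coefficients.

    ``beta_std`` multiplies each raw coefficient by SD(predictor)/SD(outcome).
    p-values come from two-sided t statistics; ``robust=True`` swaps in HC3
    heteroskedasticity-consistent standard errors, which are the safer choice
    when main effects make the Bernoulli variance differ across cells.
    """
    if isinstance(design, InteractionDesign):
        X_df, y = design.X, design.y
    else:
        X_df, y = design, np.asarray(outcome, dtype=float)
    n, k = X_df.shape
    if n <= k + 2:
        raise DegenerateDataError("too few observations for the design")
    X = np.column_stack([np.ones(n), X_df.to_numpy(dtype=float)])
    names = ["const", *X_df.columns]
    XtX = X.T @ X
    try:
        XtX_inv = np.linalg.inv(XtX)
    except np.linalg.LinAlgError as exc:
        corr = np.corrcoef(X_df.to_numpy(dtype=float).T)
        pairs = [(names[i + 1], names[j + 1]) for i in range(k) for j in range(i + 1, k)
                 if abs(corr[i, j]) > 0.999]
        raise DegenerateDataError(f"rank-deficient design; collinear columns: {pairs}") from exc
    beta = XtX_inv @ (X.T @ y)
    resid = y - X @ beta
    dof = n - (k + 1)
    if robust:
        h = np.einsum("ij,jk,ik->i", X, XtX_inv, X)
        u = resid / (1.0 - h)
        cov = XtX_inv @ ((X * (u ** 2)[:, None]).T @ X) @ XtX_inv
    else:
        s2 = float(resid @ resid) / dof
        cov = s2 * XtX_inv
    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = beta / se
    pvals = 2 * stats.t.sf(np.abs(tvals), dof)
    sd_y = y.std(ddof=1)
    sd_x = np.concatenate([[np.nan], X_df.to_numpy(dtype=float).std(axis=0, ddof=1)])
    beta_std = beta * sd_x / sd_y
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float(resid @ resid) / ss_tot if ss_tot > 0 else 0.0
    idx = pd.Index(names)
    return LinearGxeFit(pd.Series(beta, idx), pd.Series(beta_std, idx),
                        pd.Series(se, idx), pd.Series(pvals, idx), n, r2, X @ beta)


# ---------------------------------------------------------------------------
# joint-exposure stratum odds ratios and interaction verdicts


@dataclass(frozen=True)
class StratumOrSet:
    """Odds ratios of the four joint (G, E) strata against the doubly
    unexposed cell; ``cells`` maps (g, e) -> (cases, non-cases)."""

    or00: float           # always 1 (reference)
    or01: float           # genetic only
    or10: float           # environmental only
    or11: float           # both
    cells: dict
    haldane_corrected: bool = False
    incomplete: bool = False

    @property
    def reri(self) -> float:
        return self.or11 - self.or01 - self.or10 + 1.0


def stratum_ors(cohort: CohortTable, snp: SnpDef | str, exposure: str,
                genetic_coding: str = "dominant",
                population: str | None = None) -> StratumOrSet:
    """Cross-product ORs for the genetic-only, environment-only and joint
    strata, each against the doubly unexposed (G=0, E=0) reference cell.

    G is binarised by ``genetic_coding`` (default dominant: carrier of at
    least one risk allele).  The Haldane correction is applied per contrast
    when a zero cell appears, and flagged.  An empty stratum yields a result
    flagged ``incomplete`` with NaN for its OR.
    """
    design = build_interaction_design(cohort, snp, exposure, covariates=(),
                                      genetic_coding=genetic_coding,
                                      population=population)
    if "G" not in design.X.columns or "E" not in design.X.columns:
        raise DegenerateDataError("G or E constant in this stratum")
    G = (design.X["G"].to_numpy() > 0).astype(int)
    E = design.X["E"].to_numpy().astype(int)
    y = design.y.astype(bool)
    cells = {}
    for g in (0, 1):
        for e in (0, 1):
            m = (G == g) & (E == e)
            cells[(g, e)] = (int(y[m].sum()), int((~y[m]).sum()))
    return stratum_ors_from_cells(cells)


def stratum_ors_from_cells(cells: dict) -> StratumOrSet:
    """Assemble a :class:`StratumOrSet` from (g, e) -> (cases, non-cases)."""
    ref_cases, ref_non = cells[(0, 0)]
    if ref_cases + ref_non == 0:
        raise DegenerateDataError("empty reference (G=0, E=0) cell")
    corrected = False
    incomplete = False
    ors = {}
    for key, (g, e) in (("or01", (1, 0)), ("or10", (0, 1)), ("or11", (1, 1))):
        cases, non = cells[(g, e)]
        if cases + non == 0:
            ors[key] = float("nan")
            incomplete = True
            continue
        if 0 in (cases, non, ref_cases, ref_non):
            corrected = True
            a, b, c, d = cases + 0.5, non + 0.5, ref_cases + 0.5, ref_non + 0.5
        else:
            a, b, c, d = cases, non, ref_cases, ref_non
        ors[key] = (a * d) / (b * c)
    return StratumOrSet(1.0, ors["or01"], ors["or10"], ors["or11"], dict(cells),
                        haldane_corrected=corrected, incomplete=incomplete)


@dataclass(frozen=True)
class InteractionVerdict:
    multiplicative: str    # "none" | "synergistic" | "antagonistic"
    additive: str
    reri: float
    multiplicative_excess: float   # OR11 - OR01*OR10


def classify_interaction(s: StratumOrSet, tolerance: float = 0.0) -> InteractionVerdict:
    """Scale-specific interaction verdicts from the stratum ORs.

    Multiplicative: OR11 compared with OR01*OR10 — synergistic above,
    antagonistic below, none within the relative ``tolerance`` band.
    Additive: the sign of RERI = OR11 - OR01 - OR10 + 1 outside the band
    (scaled by the additive null value, floored at 1).
    """
    if not all(np.isfinite([s.or01, s.or10, s.or11])):
        return InteractionVerdict("none", "none", float("nan"), float("nan"))
    mult_null = s.or01 * s.or10
    mult_excess = s.or11 - mult_null
    mult_band = tolerance * max(abs(mult_null), 1.0)
    if mult_excess > mult_band:
        mult = "synergistic"
    elif mult_excess < -mult_band:
        mult = "antagonistic"
    else:
        mult = "none"
    reri = s.reri
    add_band = tolerance * max(abs(s.or01 + s.or10 - 1.0), 1.0)
    if reri > add_band:
        add = "synergistic"
    elif reri < -add_band:
        add = "antagonistic"
    else:
        add = "none"
    return InteractionVerdict(mult, add, reri, mult_excess)


@dataclass
class BootstrapCI:
    mult_excess_ci: tuple[float, float]
    reri_ci: tuple[float, float]
    n_resamples: int
    n_failed: int
    multiplicative_ci_verdict: str
    additive_ci_verdict: str


def bootstrap_interaction_ci(cohort: CohortTable, snp: SnpDef | str, exposure: str,
                             genetic_coding: str = "dominant",
                             population: str | None = None,
                             n_resamples: int = 2000,
                             seed: int | np.random.Generator = 0) -> BootstrapCI:
    """Seeded subject-level bootstrap percentile CI (95%) for the
    multiplicative excess OR11 - OR01*OR10 and for RERI.

    Resamples with an empty joint cell are counted as failed and skipped.
    The CI-aware verdict is "none" when the interval covers zero.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    design = build_interaction_design(cohort, snp, exposure, covariates=(),
                                      genetic_coding=genetic_coding,
                                      population=population)
    G = (design.X["G"].to_numpy() > 0).astype(int)
    E = design.X["E"].to_numpy().astype(int)
    y = design.y.astype(bool)
    n = len(y)
    mult_draws, reri_draws, failed = [], [], 0
    for _ in range(n_resamples):
        idx = rng.integers(0, n, n)
        cells = {}
        ok = True
        for g in (0, 1):
            for e in (0, 1):
                m = (G[idx] == g) & (E[idx] == e)
                cases = int(y[idx][m].sum())
                non = int(m.sum()) - cases
                if cases + non == 0:
                    ok = False
                cells[(g, e)] = (cases, non)
        if not ok:
            failed += 1
            continue
        s = stratum_ors_from_cells(cells)
        v = classify_interaction(s)
        mult_draws.append(v.multiplicative_excess)
        reri_draws.append(v.reri)
    if not mult_draws:
        raise DegenerateDataError("all bootstrap resamples degenerate")
    mult_ci = tuple(np.percentile(mult_draws, [2.5, 97.5]))
    reri_ci = tuple(np.percentile(reri_draws, [2.5, 97.5]))

    def ci_verdict(ci):
        lo, hi = ci
        if lo > 0:
            return "synergistic"
        if hi < 0:
            return "antagonistic"
        return "none"

    return BootstrapCI(mult_ci, reri_ci, n_resamples, failed,
                       ci_verdict(mult_ci), ci_verdict(reri_ci))


@dataclass
class InteractionResult:
    snp_id: str
    exposure: str
    population: str | None
    beta_std: float
    p_interaction: float
    stratum_ors: StratumOrSet
    verdict: InteractionVerdict
    bootstrap: BootstrapCI | None = None
    notes: list[str] = field(default_factory=list)


def interaction_analysis(cohort: CohortTable, snp: SnpDef | str, exposure: str,
                         population: str | None = None,
                         genetic_coding_regression: str = "dosage",
                         genetic_coding_strata: str = "dominant",
                         covariates: tuple[str, ...] = ("age",),
                         tolerance: float = 0.0,
                         bootstrap: int = 0,
                         seed: int = 0,
                         robust: bool = False) -> InteractionResult:
    """End-to-end G x E analysis for one (SNP, exposure) pair: the
    standardized linear interaction coefficient, the four-stratum ORs, and
    both scale verdicts (optionally with a bootstrap CI)."""
    include_pop = population is None
    design = build_interaction_design(cohort, snp, exposure, covariates=covariates,
                                      genetic_coding=genetic_coding_regression,
                                      include_population=include_pop,
                                      population=population)
    notes = [f"dropped constant columns: {design.dropped_columns}"] if design.dropped_columns else []
    if "GxE" in design.X.columns:
        fit = fit_gxe_linear(design, robust=robust)
        beta_std, p_int = fit.beta_std_interaction, fit.p_interaction
    else:
        beta_std, p_int = float("nan"), float("nan")
        notes.append("interaction column constant; no regression test")
    s = stratum_ors(cohort, snp, exposure, genetic_coding=genetic_coding_strata,
                    population=population)
    verdict = classify_interaction(s, tolerance=tolerance)
    boot = None
    if bootstrap:
        boot = bootstrap_interaction_ci(cohort, snp, exposure,
                                        genetic_coding=genetic_coding_strata,
                                        population=population,
                                        n_resamples=bootstrap, seed=seed)
    snp_id = snp if isinstance(snp, str) else snp.snp_id
    return InteractionResult(snp_id, exposure, population, beta_std, p_int, s,
                             verdict, boot, notes)


def interaction_report(cohort: CohortTable, exposures: tuple[str, ...],
                       population: str | None = None, tolerance: float = 0.0,
                       bootstrap: int = 0, seed: int = 0) -> pd.DataFrame:
    """Grid of interaction analyses (every panel SNP x every exposure).

    No multiple-testing adjustment is applied to the grid by default; a
    Benjamini-Hochberg column can be added downstream from ``p_interaction``.
    """
    rows = []
    for snp in cohort.panel:
        for exposure in exposures:
            try:
                r = interaction_analysis(cohort, snp, exposure, population=population,
                                         tolerance=tolerance, bootstrap=bootstrap,
                                         seed=seed)
            except DegenerateDataError as exc:
                rows.append({"snp_id": snp.snp_id, "exposure": exposure,
                             "population": population, "note": str(exc)})
                continue
            row = {
                "snp_id": r.snp_id, "exposure": exposure, "population": population,
                "beta_std": r.beta_std, "p_interaction": r.p_interaction,
                "or01": r.stratum_ors.or01, "or10": r.stratum_ors.or10,
                "or11": r.stratum_ors.or11, "reri": r.verdict.reri,
                "multiplicative": r.verdict.multiplicative,
                "additive": r.verdict.additive,
                "haldane": r.stratum_ors.haldane_corrected,
            }
            if r.bootstrap is not None:
                row["mult_ci"] = f"({r.bootstrap.mult_excess_ci[0]:.2f}, {r.bootstrap.mult_excess_ci[1]:.2f})"
                row["reri_ci"] = f"({r.bootstrap.reri_ci[0]:.2f}, {r.bootstrap.reri_ci[1]:.2f})"
            rows.append(row)
    return pd.DataFrame(rows)
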