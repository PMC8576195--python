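"""Genetic risk scores: unweighted allele counts and log-odds-weighted sums.

The unweighted score (uGRS) adds coded risk-allele dosages over the panel;
the weighted score (wGRS) multiplies each coded dosage by its external
log-odds weight.  A SNP marked ``flip`` behaves protectively, so its coding
reverses (2 - dosage).  Subjects missing any panel dosage are excluded from
scoring and counted.  Scores are dichotomised for stratified association
(default: low band 0-1 vs high >= 3, with the middle band excluded and
reported; a median cut assigns ties to the high group, matching a
">= median" rule).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .association import OddsRatio, crude_or, fit_logistic
from .cohort import CohortTable, SnpDef
from .errors import ConfigurationError, DegenerateDataError


@dataclass
class GrsConfig:
    panel: list[SnpDef]
    mode: str = "unweighted"                  # "unweighted" | "weighted"
    dichotomy_rule: str = "explicit"          # "median" | "explicit"
    explicit_high_cut: float | None = 3.0
    explicit_low_band: tuple[float, float] | None = (0.0, 1.0)

    def __post_init__(self):
        if self.mode not in ("unweighted", "weighted"):
            raise ConfigurationError(f"unknown GRS mode {self.mode!r}")
        if self.mode == "weighted":
            missing = [s.snp_id for s in self.panel if s.weight is None]
            if missing:
                raise ConfigurationError(
                    f"weighted GRS requires a weight for every SNP; missing: {missing}")


@dataclass
class GrsResult:
    scores: pd.Series                 # per subject, NaN if excluded
    mode: str
    n_excluded_missing: int
    per_population: pd.DataFrame      # mean, sd, ci_lo, ci_hi, median, n
    high_group: pd.Series             # boolean, NaN-safe (False when unscored)
    high_cut: float


def code_dosage(snp: SnpDef, raw_dosage: float) -> float:
    """Score coding of a dosage: identity, or 2 - d for a flipped (protective)
    risk allele; missing propagates."""
    if raw_dosage is None or (isinstance(raw_dosage, float) and math.isnan(raw_dosage)):
        return math.nan
    if raw_dosage not in (0, 1, 2):
        raise ValueError(f"invalid dosage {raw_dosage!r}")
    return 2.0 - raw_dosage if snp.flip else float(raw_dosage)


def compute_grs(cohort: CohortTable, config: GrsConfig) -> GrsResult:
    """Per-subject genetic risk score plus per-population summaries.

    Subjects with any missing panel dosage are excluded (score NaN) and
    counted in ``n_excluded_missing``.
    """
    if not config.panel:
        raise ConfigurationError("GRS panel is empty")
    df = cohort.data
    coded = pd.DataFrame({
        s.snp_id: [code_dosage(s, v) for v in df[s.snp_id]] for s in config.panel
    }, index=df.index)
    complete = coded.notna().all(axis=1)
    if config.mode == "weighted":
        weights = np.array([s.weight for s in config.panel], dtype=float)
        raw = coded.to_numpy() @ weights
    else:
        raw = coded.to_numpy().sum(axis=1)
    scores = pd.Series(np.where(complete, raw, np.nan), index=df.index, name="grs")

    rows = []
    for pop in ("general", "roma"):
        vals = scores[(df["population"] == pop) & complete].to_numpy(dtype=float)
        if vals.size == 0:
            rows.append({"population": pop, "n": 0})
            continue
        mean = float(vals.mean())
        sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
        se = sd / math.sqrt(vals.size)
        rows.append({"population": pop, "n": int(vals.size), "mean": mean, "sd": sd,
                     "ci_lo": mean - 1.96 * se, "ci_hi": mean + 1.96 * se,
                     "median": float(np.median(vals)),
                     "min": float(vals.min()), "max": float(vals.max())})
    per_pop = pd.DataFrame(rows)

    if config.dichotomy_rule == "median":
        cut = float(np.median(scores[complete]))
    else:
        if config.explicit_high_cut is None:
            raise ConfigurationError("explicit dichotomy requires explicit_high_cut")
        cut = float(config.explicit_high_cut)
    high = scores.ge(cut).fillna(False)  # ties at the cut go high
    return GrsResult(scores, config.mode, int((~complete).sum()), per_pop, high, cut)


@dataclass
class StratifiedOr:
    odds_ratio: OddsRatio | None
    n_low: int
    n_high: int
    n_excluded_midband: int
    cases_low: int
    cases_high: int
    separation_flag: bool
    undefined: bool = False
    notes: list[str] = field(default_factory=list)


def grs_stratified_or(cohort: CohortTable, result: GrsResult,
                      low_band: tuple[float, float] = (0.0, 1.0),
                      high_cut: float = 3.0, adjust_age: bool = False,
                      population: str | None = None) -> StratifiedOr:
    """VTE odds ratio for the high-score band (score >= ``high_cut``) versus
    the low band (inclusive interval), excluding the middle band.

    Crude estimates use the 2x2 cross-product with Woolf CI (Haldane
    corrected and flagged on zero cells); with ``adjust_age`` a logistic fit
    with age is used instead.
    """
    df = cohort.data
    mask = result.scores.notna()
    if population is not None:
        mask &= df["population"] == population
    s = result.scores[mask]
    low = (s >= low_band[0]) & (s <= low_band[1])
    high = s >= high_cut
    if not low.any() or not high.any():
        raise DegenerateDataError("empty GRS band")
    used = low | high
    n_excluded = int((~used).sum())
    vte = df.loc[s.index, "vte"].astype(bool)
    cases_high = int(vte[high].sum())
    cases_low = int(vte[low].sum())
    if cases_high == 0 and cases_low == 0:
        return StratifiedOr(None, int(low.sum()), int(high.sum()), n_excluded,
                            cases_low, cases_high, separation_flag=True, undefined=True,
                            notes=["no VTE cases in either band"])
    if adjust_age:
        sub = df.loc[s.index[used]]
        X = pd.DataFrame({"high": high[used].astype(float).to_numpy(),
                          "age": sub["age"].to_numpy(dtype=float)}, index=sub.index)
        fit = fit_logistic(X, vte[used].to_numpy())
        if fit.separation or "high" not in fit.params.index:
            oratio = crude_or(cases_high, int(high.sum()) - cases_high,
                              cases_low, int(low.sum()) - cases_low)
            return StratifiedOr(oratio, int(low.sum()), int(high.sum()), n_excluded,
                                cases_low, cases_high, separation_flag=True,
                                notes=["logistic fit separated; crude Haldane OR reported"])
        oratio = fit.odds_ratio("high")
        sep = False
    else:
        oratio = crude_or(cases_high, int(high.sum()) - cases_high,
                          cases_low, int(low.sum()) - cases_low)
        sep = oratio.haldane_corrected
    return StratifiedOr(oratio, int(low.sum()), int(high.sum()), n_excluded,
                        cases_low, cases_high, separation_flag=sep)


def grs_env_joint_or(cohort: CohortTable, result: GrsResult, env_flag: str,
                     high_cut: float | None = None, adjust_age: bool = False,
                     population: str | None = None) -> StratifiedOr:
    """VTE odds ratio for an environmental factor within the high-score stratum.

    This is the additive-effect screen: among subjects whose score reaches
    the high cut, does the exposure raise VTE odds?
    """
    df = cohort.data
    cut = result.high_cut if high_cut is None else high_cut
    mask = result.scores.notna() & result.scores.ge(cut)
    if population is not None:
        mask &= df["population"] == population
    sub = df[mask]
    if sub.empty:
        raise DegenerateDataError("empty high-GRS stratum")
    if env_flag not in sub.columns:
        raise ConfigurationError(f"unknown environmental flag {env_flag!r}")
    e = sub[env_flag].astype(bool).to_numpy()
    if e.all() or not e.any():
        raise DegenerateDataError(f"{env_flag!r} constant within the high-GRS stratum")
    vte = sub["vte"].astype(bool).to_numpy()
    ce, ne = int(vte[e].sum()), int((~vte[e]).sum())
    cu, nu = int(vte[~e].sum()), int((~vte[~e]).sum())
    if adjust_age:
        X = pd.DataFrame({"env": e.astype(float), "age": sub["age"].to_numpy(dtype=float)})
        fit = fit_logistic(X, vte)
        if not fit.separation and "env" in fit.params.index:
            return StratifiedOr(fit.odds_ratio("env"), int((~e).sum()), int(e.sum()), 0,
                                cu, ce, separation_flag=False)
    oratio = crude_or(ce, ne, cu, nu)
    return StratifiedOr(oratio, int((~e).sum()), int(e.sum()), 0, cu, ce,
                        separation_flag=oratio.haldane_corrected)


def score_frame(cohort: CohortTable, result: GrsResult) -> pd.DataFrame:
    """One row per subject: id, population, score, band membership."""
    df = cohort.data
    return pd.DataFrame({
        "subject_id": df["subject_id"],
        "population": df["population"],
        f"{result.mode}_grs": result.scores,
        "high_group": result.high_group,
    })
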