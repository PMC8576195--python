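"""Synthetic-cohort generation.

Two generators:

* :func:`generate_cohort` draws cohorts with the statistical structure the
  analysis assumes — Hardy-Weinberg genotypes at configurable per-population
  risk-allele frequencies (no linkage disequilibrium), normal covariates
  (triglycerides optionally log-normal, to exercise the rank-based
  normalisation), Bernoulli condition flags, and a logistic outcome model
  with configurable main-effect, interaction, and age coefficients.  The
  defaults reproduce the published study conditions: two populations of
  406/395 subjects, the published allele frequencies (including a founder
  allele at 1% in one population and absent in the other), the published
  covariate means, and a baseline VTE prevalence of 1.5% / 3.0%.

* :func:`make_study_fixture` rebuilds a deterministic cohort whose per-SNP
  genotype x outcome x population counts (and the outcome x sex margins)
  exactly equal the published tables, with covariates filled at population
  means — suitable for count-level analyses only, since the joint genotype
  distribution across SNPs is not published.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import reference
from .cohort import CohortTable, SnpDef, default_panel
from .errors import ConfigurationError

#: nominal condition prevalences (not published for the study cohort;
#: chosen as survey-plausible adult values and clearly synthetic)
DEFAULT_CONDITION_PREVALENCE = {
    "cancer": {"general": 0.02, "roma": 0.02},
    "dm": {"general": 0.08, "roma": 0.10},
    "cad": {"general": 0.05, "roma": 0.06},
    "ckd": {"general": 0.02, "roma": 0.02},
    "migraine": {"general": 0.10, "roma": 0.12},
    "depression": {"general": 0.10, "roma": 0.12},
    "current_smoker": {"general": 0.30, "roma": 0.50},
    "quit_lt1y": {"general": 0.03, "roma": 0.03},
    "quit_ge1y": {"general": 0.15, "roma": 0.08},
}

DEFAULT_BASELINE_PREVALENCE = {"general": 0.015, "roma": 0.030}


def _logit(p: float) -> float:
    return float(np.log(p / (1.0 - p)))


@dataclass
class OutcomeModel:
    """Logistic model for the VTE outcome.

    ``intercept`` is per-population (log-odds at zero for all predictors);
    ``snp_effects`` maps rsID -> log-odds per risk-allele copy;
    ``env_effects`` maps a condition/exposure name -> log-odds;
    ``interactions`` maps (rsID, exposure) -> log-odds on the product term;
    ``age_effect`` is log-odds per year of centred age.
    """

    intercept: dict[str, float] = field(
        default_factory=lambda: {p: _logit(v) for p, v in DEFAULT_BASELINE_PREVALENCE.items()})
    snp_effects: dict[str, float] = field(default_factory=dict)
    env_effects: dict[str, float] = field(default_factory=dict)
    interactions: dict[tuple[str, str], float] = field(default_factory=dict)
    age_effect: float = 0.0


@dataclass
class GeneratorSpec:
    """Full description of a synthetic two-population cohort."""

    n: dict[str, int] = field(default_factory=lambda: dict(reference.POPULATION_N))
    panel: list[SnpDef] = field(default_factory=default_panel)
    allele_freqs: dict[str, dict[str, float]] = field(
        default_factory=lambda: {s: dict(f) for s, f in reference.RISK_ALLELE_FREQ.items()})
    covariates: dict[str, dict[str, tuple[float, float]]] = field(default_factory=lambda: {
        cov: {pop: (reference.COVARIATE_SUMMARY[cov][pop][0],
                    reference.covariate_sd(cov, pop))
              for pop in reference.POPULATIONS}
        for cov in reference.QUANTITATIVE_COVARIATES})
    female_fraction: dict[str, float] = field(
        default_factory=lambda: dict(reference.FEMALE_FRACTION))
    condition_prevalence: dict[str, dict[str, float]] = field(
        default_factory=lambda: {c: dict(p) for c, p in DEFAULT_CONDITION_PREVALENCE.items()})
    outcome: OutcomeModel = field(default_factory=OutcomeModel)
    tg_lognormal: bool = True
    age_range: tuple[float, float] = (20.0, 64.0)

    def validate(self) -> None:
        for pop, n in self.n.items():
            if n < 1:
                raise ConfigurationError(f"population {pop!r}: N must be >= 1")
        for snp_id, freqs in self.allele_freqs.items():
            for pop, p in freqs.items():
                if not 0.0 <= p <= 1.0:
                    raise ConfigurationError(f"{snp_id}/{pop}: frequency {p} outside [0, 1]")
        for pop, b in self.outcome.intercept.items():
            prev = 1.0 / (1.0 + np.exp(-b))
            if not 0.0 < prev < 1.0:
                raise ConfigurationError(f"{pop}: baseline prevalence outside (0, 1)")

    def with_effects(self, **kwargs) -> "GeneratorSpec":
        """Copy of the spec with outcome-model fields replaced."""
        return replace(self, outcome=replace(self.outcome, **kwargs))


def generate_genotypes(spec: GeneratorSpec, population: str,
                       rng: np.random.Generator) -> pd.DataFrame:
    """Hardy-Weinberg genotypes: dosage ~ Binomial(2, p) independently per
    SNP and subject (no linkage disequilibrium)."""
    spec.validate()
    n = spec.n[population]
    cols = {}
    for snp in spec.panel:
        p = spec.allele_freqs[snp.snp_id][population]
        cols[snp.snp_id] = rng.binomial(2, p, size=n).astype(float)
    return pd.DataFrame(cols)


def generate_phenotypes(spec: GeneratorSpec, population: str,
                        dosages: pd.DataFrame, rng: np.random.Generator,
                        id_prefix: str = "") -> pd.DataFrame:
    """Covariates, condition flags, and the logistic VTE outcome for one
    population, given a dosage matrix.

    Quantitative covariates are normal at the spec's means/SDs, truncated to
    plausible supports; triglycerides are log-normal (moment-matched) when
    ``tg_lognormal`` is set.  Obesity derives from BMI > 30; other
    conditions are independent Bernoulli draws unless an outcome coefficient
    links them to VTE.
    """
    n = len(dosages)
    df = pd.DataFrame({
        "subject_id": [f"{id_prefix}{population}_{i:06d}" for i in range(n)],
        "population": population,
    })
    female = rng.random(n) < spec.female_fraction[population]
    df["sex"] = np.where(female, "female", "male")
    lo, hi = spec.age_range
    age_mean, age_sd = spec.covariates["age"][population]
    df["age"] = np.clip(rng.normal(age_mean, age_sd, n), lo, hi)
    for cov, per_pop in spec.covariates.items():
        if cov == "age":
            continue
        mean, sd = per_pop[population]
        if cov == "tg" and spec.tg_lognormal and sd > 0:
            sigma2 = np.log(1.0 + (sd / mean) ** 2)
            mu = np.log(mean) - sigma2 / 2.0
            vals = rng.lognormal(mu, np.sqrt(sigma2), n)
        else:
            vals = rng.normal(mean, sd, n)
        df[cov] = np.clip(vals, 0.05, None) if sd > 0 else np.full(n, mean)
    for cond, per_pop in spec.condition_prevalence.items():
        df[cond] = rng.random(n) < per_pop[population]
    df["obesity"] = df["bmi"] > 30.0

    model = spec.outcome
    lp = np.full(n, model.intercept[population])
    lp += model.age_effect * (df["age"].to_numpy() - age_mean)
    for snp_id, beta in model.snp_effects.items():
        lp += beta * dosages[snp_id].to_numpy()
    from .gxe import binarize_exposure
    for env, beta in model.env_effects.items():
        lp += beta * binarize_exposure(df, env)
    for (snp_id, env), beta in model.interactions.items():
        lp += beta * dosages[snp_id].to_numpy() * binarize_exposure(df, env)
    prev = 1.0 / (1.0 + np.exp(-lp))
    if prev.min() <= 0.0 or prev.max() >= 1.0:
        raise ConfigurationError(
            "outcome prevalence saturates 0 or 1; lower the intercept or effect sizes")
    df["vte"] = rng.random(n) < prev
    return pd.concat([df, dosages.set_index(df.index)], axis=1)


def generate_cohort(spec: GeneratorSpec | None = None,
                    seed: int | np.random.Generator = 0) -> CohortTable:
    """Draw a complete two-population cohort.  Deterministic given the spec
    and seed."""
    spec = spec if spec is not None else GeneratorSpec()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    frames = []
    for pop in spec.n:
        dosages = generate_genotypes(spec, pop, rng)
        frames.append(generate_phenotypes(spec, pop, dosages, rng))
    data = pd.concat(frames, ignore_index=True)
    return CohortTable(data, spec.panel)


# ---------------------------------------------------------------------------
# deterministic fixture reproducing the published counts


def make_study_fixture(panel: list[SnpDef] | None = None) -> CohortTable:
    """A deterministic cohort matching every published genotype x VTE x
    population count and the VTE x sex margins.

    Within each population, VTE cases come first (males before females),
    then non-cases (males before females); each SNP's genotype counts are
    assigned blockwise over that fixed order, independently per SNP.  Ages
    and covariates are filled with published population means, so the
    fixture supports count-level analyses only — the joint distribution
    across SNPs and any covariate variation are synthetic conveniences.
    """
    panel = panel if panel is not None else default_panel()
    frames = []
    for pop in reference.POPULATIONS:
        sex_counts = reference.VTE_SEX_COUNTS[pop]
        order = []  # (sex, vte)
        for sex in ("male", "female"):
            order.extend([(sex, True)] * sex_counts[sex][0])
        for sex in ("male", "female"):
            order.extend([(sex, False)] * sex_counts[sex][1])
        n = len(order)
        assert n == reference.POPULATION_N[pop]
        df = pd.DataFrame({
            "subject_id": [f"fx_{pop}_{i:04d}" for i in range(n)],
            "population": pop,
            "sex": [s for s, _ in order],
            "vte": [v for _, v in order],
        })
        df["age"] = reference.COVARIATE_SUMMARY["age"][pop][0]
        for cov in reference.QUANTITATIVE_COVARIATES:
            if cov != "age":
                df[cov] = reference.COVARIATE_SUMMARY[cov][pop][0]
        for cond in reference.CONDITION_FLAGS:
            df[cond] = False
        n_cases = int(df["vte"].sum())
        for snp in panel:
            cells = reference.GENOTYPE_VTE_COUNTS[snp.snp_id][pop]
            col = np.full(n, np.nan)
            col[:n_cases] = _blockwise([(d, cells.get(d, (0, 0))[0]) for d in (0, 1, 2)])
            col[n_cases:] = _blockwise([(d, cells.get(d, (0, 0))[1]) for d in (0, 1, 2)])
            df[snp.snp_id] = col
        frames.append(df)
    return CohortTable(pd.concat(frames, ignore_index=True), panel)


def _blockwise(blocks: list[tuple[int, int]]) -> np.ndarray:
    return np.concatenate([np.full(count, float(d)) for d, count in blocks]) \
        if any(c for _, c in blocks) else np.empty(0)
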