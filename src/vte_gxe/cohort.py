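"""Cohort data model: SNP panel definitions, per-subject records, IO, validation.

A cohort is a rectangular table with one row per subject carrying a
population label (``general`` or ``roma``), sex, age, quantitative
covariates, binary condition flags, a binary VTE outcome, and one genotype
column per SNP in the panel.  Genotypes are normalised internally to the
*risk-allele dosage* (0, 1 or 2 copies of the risk allele); text files may
supply them as allele pairs ("G/A" or "GA"), as integers, or leave them
missing.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import GenotypeParseError, SchemaError, ValidationError
from . import reference

MISSING_TOKENS = {"", ".", "na", "nan", "none", "./.", "-"}

REQUIRED_COLUMNS = (
    "subject_id",
    "population",
    "sex",
    "age",
    "vte",
)

DEFAULT_AGE_RANGE = (20.0, 64.0)

_TRUE_TOKENS = {"1", "true", "yes", "y", "t"}
_FALSE_TOKENS = {"0", "false", "no", "n", "f"}


@dataclass(frozen=True)
class SnpDef:
    """Identity and risk-allele orientation of one biallelic SNP.

    Parameters
    ----------
    snp_id : rsID string.
    gene : gene symbol, for reporting only.
    alleles : the two allele symbols, reference-orientation order.
    risk_allele : which of ``alleles`` raises outcome odds; dosage counts
        copies of this allele.
    weight : optional external log-odds weight for the weighted risk score.
    flip : if True the nominal risk allele behaves protectively and dosage
        coding for scores is reversed (2 - d).
    """

    snp_id: str
    gene: str
    alleles: tuple[str, str]
    risk_allele: str
    weight: float | None = None
    flip: bool = False

    def __post_init__(self):
        if self.risk_allele not in self.alleles:
            raise ValidationError(
                f"{self.snp_id}: risk allele {self.risk_allele!r} not among alleles {self.alleles}"
            )
        if self.weight is not None and not math.isfinite(self.weight):
            raise ValidationError(f"{self.snp_id}: weight must be finite")

    @property
    def other_allele(self) -> str:
        a, b = self.alleles
        return b if self.risk_allele == a else a

    def swapped(self) -> "SnpDef":
        """The same SNP with risk-allele orientation reversed."""
        return replace(self, risk_allele=self.other_allele)


def default_panel() -> list[SnpDef]:
    """The bundled six-SNP prothrombotic panel with placeholder weights."""
    return [
        SnpDef(snp_id, gene, alleles, alleles[1], weight=weight)
        for snp_id, (gene, alleles, weight) in reference.SNP_PANEL.items()
    ]


def read_snp_config(path: str | Path) -> list[SnpDef]:
    """Load a SNP panel from a YAML file.

    Expected layout::

        snps:
          - snp_id: rs6025
            gene: F5
            alleles: [C, T]
            risk_allele: T
            weight: 0.88      # optional, log-odds
            flip: false       # optional
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "snps" not in doc:
        raise SchemaError(f"{path}: expected a mapping with a 'snps' list")
    panel = []
    for entry in doc["snps"]:
        try:
            panel.append(
                SnpDef(
                    snp_id=str(entry["snp_id"]),
                    gene=str(entry.get("gene", "")),
                    alleles=tuple(str(a) for a in entry["alleles"]),
                    risk_allele=str(entry["risk_allele"]),
                    weight=None if entry.get("weight") is None else float(entry["weight"]),
                    flip=bool(entry.get("flip", False)),
                )
            )
        except KeyError as exc:
            raise SchemaError(f"{path}: SNP entry missing key {exc}") from exc
    return panel


def write_snp_config(panel: Iterable[SnpDef], path: str | Path) -> None:
    doc = {
        "snps": [
            {
                "snp_id": s.snp_id,
                "gene": s.gene,
                "alleles": list(s.alleles),
                "risk_allele": s.risk_allele,
                "weight": s.weight,
                "flip": s.flip,
            }
            for s in panel
        ]
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


@dataclass
class CohortTable:
    """A validated cohort: subject table plus the SNP panel it was typed on.

    ``data`` holds one row per subject; genotype columns (named by rsID)
    contain float risk-allele dosages with NaN for missing.  ``vte`` and
    condition flags are boolean.
    """

    data: pd.DataFrame
    panel: list[SnpDef] = field(default_factory=default_panel)

    def __post_init__(self):
        self.validate()

    # -- contracts ---------------------------------------------------------
    def validate(self, age_range: tuple[float, float] = DEFAULT_AGE_RANGE) -> None:
        df = self.data
        for col in REQUIRED_COLUMNS:
            if col not in df.columns:
                raise SchemaError(f"cohort table lacks required column {col!r}")
        if df["subject_id"].duplicated().any():
            dup = df.loc[df["subject_id"].duplicated(), "subject_id"].iloc[0]
            raise ValidationError(f"duplicate subject_id {dup!r}")
        bad_pop = set(df["population"]) - set(reference.POPULATIONS)
        if bad_pop:
            raise ValidationError(f"unknown population labels {sorted(bad_pop)}")
        lo, hi = age_range
        ages = df["age"].to_numpy(dtype=float)
        if np.nanmin(ages) < lo or np.nanmax(ages) > hi:
            raise ValidationError(f"age outside plausible range [{lo}, {hi}]")
        for snp in self.panel:
            if snp.snp_id not in df.columns:
                raise SchemaError(f"cohort table lacks genotype column {snp.snp_id!r}")
            d = df[snp.snp_id].to_numpy(dtype=float)
            ok = np.isnan(d) | np.isin(d, (0.0, 1.0, 2.0))
            if not ok.all():
                raise ValidationError(
                    f"{snp.snp_id}: dosage outside {{0,1,2,missing}} at row {int(np.flatnonzero(~ok)[0])}"
                )

    # -- convenience -------------------------------------------------------
    @property
    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.panel]

    def snp(self, snp_id: str) -> SnpDef:
        for s in self.panel:
            if s.snp_id == snp_id:
                return s
        raise KeyError(snp_id)

    def stratum(self, population: str) -> pd.DataFrame:
        return self.data[self.data["population"] == population]

    def __len__(self) -> int:
        return len(self.data)


# ---------------------------------------------------------------------------
# genotype text parsing


def parse_genotype(token, snp: SnpDef, row: int | None = None) -> float:
    """Interpret one genotype cell as a risk-allele dosage.

    Accepts integer dosages (0/1/2), slash-separated allele pairs ("G/A"),
    and concatenated pairs ("GA"); missing tokens map to NaN.
    """
    if token is None or (isinstance(token, float) and math.isnan(token)):
        return math.nan
    text = str(token).strip()
    if text.lower() in MISSING_TOKENS:
        return math.nan
    if text in {"0", "1", "2"} or text in {"0.0", "1.0", "2.0"}:
        return float(int(float(text)))
    if "/" in text:
        parts = text.split("/")
    else:
        parts = _split_concatenated(text, snp, row)
    if len(parts) != 2:
        raise GenotypeParseError(f"{snp.snp_id}: cannot parse genotype {text!r}", row)
    for allele in parts:
        if allele not in snp.alleles:
            raise GenotypeParseError(
                f"{snp.snp_id}: unknown allele {allele!r} in genotype {text!r}", row
            )
    return float(sum(a == snp.risk_allele for a in parts))


def _split_concatenated(text: str, snp: SnpDef, row: int | None) -> list[str]:
    a, b = snp.alleles
    for first, second in ((a, a), (a, b), (b, a), (b, b)):
        if text == first + second:
            return [first, second]
    raise GenotypeParseError(f"{snp.snp_id}: cannot parse genotype {text!r}", row)


def format_genotype(dosage: float, snp: SnpDef) -> str:
    if math.isnan(dosage):
        return "."
    d = int(dosage)
    risk, other = snp.risk_allele, snp.other_allele
    return {0: f"{other}/{other}", 1: f"{other}/{risk}", 2: f"{risk}/{risk}"}[d]


# ---------------------------------------------------------------------------
# readers / writers


def _coerce_bool(series: pd.Series, name: str) -> pd.Series:
    if series.dtype == bool:
        return series
    out = []
    for i, v in enumerate(series):
        text = str(v).strip().lower()
        if text in _TRUE_TOKENS:
            out.append(True)
        elif text in _FALSE_TOKENS:
            out.append(False)
        else:
            raise ValidationError(f"column {name!r}: non-boolean value {v!r} at row {i}")
    return pd.Series(out, index=series.index)


def read_cohort(path: str | Path, snp_config: str | Path | None = None,
                panel: list[SnpDef] | None = None) -> CohortTable:
    """Read a delimited cohort file (comma or tab, autodetected).

    ``snp_config`` points at a YAML panel definition; alternatively pass a
    ``panel`` directly.  Genotype columns are converted to risk-allele
    dosages according to each SNP's orientation.
    """
    if panel is None:
        panel = read_snp_config(snp_config) if snp_config else default_panel()
    raw = Path(path).read_text()
    sep = "\t" if "\t" in raw.splitlines()[0] else ","
    df = pd.read_csv(io.StringIO(raw), sep=sep, dtype={"subject_id": str},
                     keep_default_na=False, na_values=[])
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    df["age"] = pd.to_numeric(df["age"])
    df["vte"] = _coerce_bool(df["vte"], "vte")
    for flag in reference.CONDITION_FLAGS:
        if flag in df.columns:
            df[flag] = _coerce_bool(df[flag], flag)
    for cov in reference.QUANTITATIVE_COVARIATES:
        if cov in df.columns and cov != "age":
            df[cov] = pd.to_numeric(df[cov], errors="coerce")
    for snp in panel:
        if snp.snp_id in df.columns:
            df[snp.snp_id] = [
                parse_genotype(v, snp, row=i) for i, v in enumerate(df[snp.snp_id])
            ]
    return CohortTable(df, panel)


def write_cohort(cohort: CohortTable, path: str | Path, genotypes: str = "dosage",
                 sep: str = "\t") -> None:
    """Write a cohort back to delimited text.

    ``genotypes`` is ``"dosage"`` (integers, missing as empty) or
    ``"pairs"`` (allele pairs like ``G/A``).
    """
    df = cohort.data.copy()
    for snp in cohort.panel:
        col = df[snp.snp_id]
        if genotypes == "pairs":
            df[snp.snp_id] = [format_genotype(v, snp) for v in col]
        else:
            df[snp.snp_id] = ["" if math.isnan(v) else str(int(v)) for v in col]
    for flag in ("vte", *reference.CONDITION_FLAGS):
        if flag in df.columns:
            df[flag] = df[flag].astype(int)
    df.to_csv(path, sep=sep, index=False)


def read_vcf_genotypes(path: str | Path, panel: list[SnpDef]) -> pd.DataFrame:
    """Extract risk-allele dosages for panel rsIDs from a VCF (GT field only).

    Returns a DataFrame (samples x rsIDs).  Requires ``cyvcf2``; any VCF
    record whose ID is not in the panel is ignored.
    """
    from cyvcf2 import VCF  # optional dependency

    wanted = {s.snp_id: s for s in panel}
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    columns: dict[str, np.ndarray] = {}
    for record in vcf:
        snp = wanted.get(record.ID)
        if snp is None:
            continue
        # gt_types: 0 hom-ref, 1 het, 3 hom-alt, 2 unknown
        alt_dosage = np.where(
            record.gt_types == 2, np.nan, np.select(
                [record.gt_types == 0, record.gt_types == 1, record.gt_types == 3],
                [0.0, 1.0, 2.0],
            )
        )
        # orient: VCF ALT is alleles[1] by convention of the panel config
        if snp.risk_allele == snp.alleles[0]:
            alt_dosage = 2.0 - alt_dosage
        columns[snp.snp_id] = alt_dosage
    return pd.DataFrame(columns, index=samples)


# ---------------------------------------------------------------------------
# descriptive summaries


@dataclass
class PopulationSummary:
    population: str
    n: int
    female_pct: float | None
    covariates: dict[str, tuple[float | None, float | None, float | None]]
    vte_by_sex: dict[str, tuple[int, int, float | None]]
    vte_cases: int
    vte_pct: float | None


def summarize_cohort(cohort: CohortTable) -> dict[str, PopulationSummary]:
    """Per-population descriptives: N, % female, covariate means with 95% CI,
    and VTE counts/percentages by sex and overall.

    Empty strata are reported with N = 0 and absent statistics.
    """
    out: dict[str, PopulationSummary] = {}
    for pop in reference.POPULATIONS:
        df = cohort.stratum(pop)
        n = len(df)
        if n == 0:
            out[pop] = PopulationSummary(pop, 0, None, {}, {}, 0, None)
            continue
        female_pct = 100.0 * (df["sex"] == "female").mean()
        covs = {}
        for cov in reference.QUANTITATIVE_COVARIATES:
            if cov not in df.columns:
                continue
            vals = df[cov].dropna().to_numpy(dtype=float)
            if vals.size == 0:
                covs[cov] = (None, None, None)
                continue
            mean = float(vals.mean())
            se = float(vals.std(ddof=1) / math.sqrt(vals.size)) if vals.size > 1 else 0.0
            covs[cov] = (mean, mean - 1.96 * se, mean + 1.96 * se)
        vte_by_sex = {}
        for sex in ("male", "female"):
            sub = df[df["sex"] == sex]
            cases = int(sub["vte"].sum())
            non = len(sub) - cases
            pct = 100.0 * cases / len(sub) if len(sub) else None
            vte_by_sex[sex] = (cases, non, pct)
        cases = int(df["vte"].sum())
        out[pop] = PopulationSummary(
            pop, n, female_pct, covs, vte_by_sex, cases, 100.0 * cases / n
        )
    return out


def summary_frame(summaries: Mapping[str, PopulationSummary]) -> pd.DataFrame:
    """Flatten summaries into a tidy frame (one row per population/statistic)."""
    rows = []
    for pop, s in summaries.items():
        rows.append({"population": pop, "statistic": "n", "value": s.n})
        rows.append({"population": pop, "statistic": "female_pct", "value": s.female_pct})
        rows.append({"population": pop, "statistic": "vte_pct", "value": s.vte_pct})
        for cov, (mean, lo, hi) in s.covariates.items():
            rows.append({"population": pop, "statistic": f"{cov}_mean", "value": mean,
                         "ci_lo": lo, "ci_hi": hi})
    return pd.DataFrame(rows)
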