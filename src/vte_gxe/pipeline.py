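"""Pipeline orchestration: simulate/ingest -> describe -> popgen ->
association -> risk scores -> gene-environment interaction -> report bundle.

Every stage writes a plain delimited-text report into the output directory,
plus a JSON manifest recording versions, the seed, a hash of the effective
configuration, and exclusion counts — rerunning with the same configuration
is bit-identical for deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .association import association_report
from .cohort import CohortTable, read_cohort, summarize_cohort, summary_frame
from .errors import ConfigurationError
from .grs import GrsConfig, compute_grs, score_frame
from .gxe import interaction_report
from .popgen import frequency_report
from .simulate import GeneratorSpec, generate_cohort, make_study_fixture

STAGES = ("describe", "popgen", "assoc", "grs", "gxe")

DEFAULT_EXPOSURES = ("cancer", "dm", "cad", "ckd", "migraine", "depression",
                     "current_smoker", "obesity", "tc", "ldl_c", "hdl_c", "tg")


@dataclass
class RunConfig:
    input_path: str | None = None          # cohort file; None -> simulate/fixture
    snp_config: str | None = None
    source: str = "simulate"               # "simulate" | "fixture" | "file"
    generator: GeneratorSpec | None = None
    stages: tuple[str, ...] = STAGES
    alpha: float = 0.05
    bonferroni_m: int = 6
    exposures: tuple[str, ...] = DEFAULT_EXPOSURES
    grs_low_band: tuple[float, float] = (0.0, 1.0)
    grs_high_cut: float = 3.0
    bootstrap: int = 0
    out_dir: str = "vte_gxe_out"
    seed: int = 0

    def validate(self) -> None:
        order = {s: i for i, s in enumerate(STAGES)}
        idx = [order.get(s) for s in self.stages]
        if any(i is None for i in idx):
            raise ConfigurationError(f"unknown stage in {self.stages}")
        if sorted(idx) != idx:
            raise ConfigurationError("stages must respect the pipeline order")


def _config_digest(config: RunConfig) -> str:
    # hash only analysis-relevant settings, not where reports land
    blob = json.dumps({k: repr(v) for k, v in vars(config).items() if k != "out_dir"},
                      sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_input(config: RunConfig) -> CohortTable:
    if config.source == "file":
        if config.input_path is None:
            raise ConfigurationError("source 'file' requires input_path")
        return read_cohort(config.input_path, snp_config=config.snp_config)
    if config.source == "fixture":
        return make_study_fixture()
    if config.source == "simulate":
        spec = config.generator if config.generator is not None else GeneratorSpec()
        return generate_cohort(spec, seed=np.random.default_rng(config.seed))
    raise ConfigurationError(f"unknown source {config.source!r}")


def run_pipeline(config: RunConfig, cohort: CohortTable | None = None) -> dict:
    """Execute the configured stages; returns {stage: DataFrame} plus writes
    TSV reports and a manifest under ``config.out_dir``."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if cohort is None:
        cohort = load_input(config)

    reports: dict[str, pd.DataFrame] = {}
    exclusions: dict[str, int] = {}
    if "describe" in config.stages:
        reports["describe"] = summary_frame(summarize_cohort(cohort))
    if "popgen" in config.stages:
        reports["popgen"] = frequency_report(cohort, alpha=config.alpha)
    if "assoc" in config.stages:
        reports["assoc"] = association_report(cohort, adjust_age=True)
    if "grs" in config.stages:
        frames = []
        for mode in ("unweighted", "weighted"):
            panel = cohort.panel if mode == "unweighted" else [
                s for s in cohort.panel if s.weight is not None]
            result = compute_grs(cohort, GrsConfig(panel, mode=mode))
            exclusions[f"grs_{mode}_missing"] = result.n_excluded_missing
            sf = score_frame(cohort, result)
            sf = sf.rename(columns={f"{mode}_grs": "score"})
            sf.insert(2, "mode", mode)
            frames.append(sf)
        reports["grs"] = pd.concat(frames, ignore_index=True)
    if "gxe" in config.stages:
        frames = [interaction_report(cohort, config.exposures, population=pop,
                                     bootstrap=config.bootstrap, seed=config.seed)
                  for pop in ("general", "roma")]
        reports["gxe"] = pd.concat(frames, ignore_index=True)

    for stage, frame in reports.items():
        frame.to_csv(out / f"{stage}.tsv", sep="\t", index=False)

    manifest = {
        "package_version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "source": config.source,
        "stages": list(config.stages),
        "alpha": config.alpha,
        "bonferroni_m": config.bonferroni_m,
        "grs_low_band": list(config.grs_low_band),
        "grs_high_cut": config.grs_high_cut,
        "bootstrap": config.bootstrap,
        "config_sha256": _config_digest(config),
        "n_subjects": len(cohort),
        "exclusions": exclusions,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    reports["manifest"] = manifest
    return reports
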