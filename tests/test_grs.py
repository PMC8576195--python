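"""Genetic risk scores: coding, bounds, orientation invariance, distribution,
and score-stratified odds ratios against the generating model."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import vte_gxe as vg
from vte_gxe.errors import ConfigurationError


def snp(flip=False, weight=None):
    return vg.SnpDef("rs_x", "X", ("G", "A"), "A", weight=weight, flip=flip)


@pytest.mark.parametrize("flip,raw,expected", [
    (False, 2, 2), (False, 0, 0), (True, 2, 0), (True, 0, 2), (True, 1, 1),
])
def test_code_dosage(flip, raw, expected):
    assert vg.code_dosage(snp(flip=flip), raw) == expected


def test_code_dosage_propagates_missing():
    assert math.isnan(vg.code_dosage(snp(), float("nan")))


def test_ugrs_bounds_and_arithmetic(study_fixture):
    result = vg.compute_grs(study_fixture, vg.GrsConfig(study_fixture.panel))
    scores = result.scores.dropna()
    m = len(study_fixture.panel)
    assert scores.between(0, 2 * m).all()
    assert (scores == scores.round()).all()


def test_wgrs_weighted_sum_example():
    weights = (0.5, 0.3, 0.2, 0.1, 0.4)
    dosages = (1, 0, 2, 0, 1)
    panel = [vg.SnpDef(f"rs{i}", "G", ("G", "A"), "A", weight=w)
             for i, w in enumerate(weights)]
    import pandas as pd
    df = pd.DataFrame({
        "subject_id": ["s1"], "population": ["roma"], "sex": ["female"],
        "age": [40.0], "vte": [False],
        **{f"rs{i}": [float(d)] for i, d in enumerate(dosages)},
    })
    cohort = vg.CohortTable(df, panel)
    result = vg.compute_grs(cohort, vg.GrsConfig(panel, mode="weighted"))
    assert result.scores.iloc[0] == pytest.approx(1.3)


def test_weighted_mode_requires_weights(panel):
    with pytest.raises(ConfigurationError, match="rs121909567"):
        vg.GrsConfig(panel, mode="weighted")


def test_orientation_invariance(small_cohort):
    """Swapping a SNP's allele labels in the data while toggling its flip
    flag leaves every subject's score unchanged."""
    base = vg.compute_grs(small_cohort, vg.GrsConfig(small_cohort.panel)).scores
    target = small_cohort.panel[3]
    df = small_cohort.data.copy()
    df[target.snp_id] = 2.0 - df[target.snp_id]
    import dataclasses
    flipped_panel = [
        dataclasses.replace(s.swapped(), flip=not s.flip) if s.snp_id == target.snp_id else s
        for s in small_cohort.panel]
    flipped = vg.compute_grs(vg.CohortTable(df, flipped_panel),
                             vg.GrsConfig(flipped_panel)).scores
    assert np.allclose(base.to_numpy(), flipped.to_numpy(), equal_nan=True)


def test_missing_dosage_excluded_and_counted(small_cohort):
    df = small_cohort.data.copy()
    df.loc[df.index[:7], small_cohort.panel[0].snp_id] = np.nan
    cohort = vg.CohortTable(df, small_cohort.panel)
    result = vg.compute_grs(cohort, vg.GrsConfig(cohort.panel))
    assert result.n_excluded_missing == 7
    assert result.scores.isna().sum() == 7


def test_median_cut_ties_go_high(small_cohort):
    result = vg.compute_grs(small_cohort,
                            vg.GrsConfig(small_cohort.panel, dichotomy_rule="median"))
    scores = result.scores.dropna()
    high_prev = result.high_group[scores.index].mean()
    assert 0.5 <= high_prev <= 1.0
    assert (scores[result.high_group[scores.index]] >= result.high_cut).all()


def test_ugrs_distribution_matches_binomial_convolution():
    """On an HWE cohort the unweighted score distribution is the convolution
    of per-SNP Binomial(2, p) dosage distributions."""
    spec = vg.GeneratorSpec()
    spec.n = {"roma": 100_000}
    cohort = vg.generate_cohort(spec, seed=2024)
    result = vg.compute_grs(cohort, vg.GrsConfig(cohort.panel))
    scores = result.scores.to_numpy()
    pmf = np.array([1.0])
    for s in cohort.panel:
        p = spec.allele_freqs[s.snp_id]["roma"]
        per = np.array([(1 - p) ** 2, 2 * p * (1 - p), p ** 2])
        pmf = np.convolve(pmf, per)
    observed = np.bincount(scores.astype(int), minlength=pmf.size)
    expected = pmf * scores.size
    keep = expected > 5
    chi2 = ((observed[keep] - expected[keep]) ** 2 / expected[keep]).sum()
    chi2 += (observed[~keep].sum() - expected[~keep].sum()) ** 2 / max(expected[~keep].sum(), 1)
    dof = keep.sum()  # pooled tail adds one cell, minus one constraint
    assert stats.chi2.sf(chi2, dof) > 1e-4


def test_stratified_or_recovers_planted_band_effect():
    """Plant a log-OR of 1.0 between the low and high score bands and check
    the estimate against the generating model (binomial-SE bound)."""
    spec = vg.GeneratorSpec()
    spec.n = {"roma": 50_000}
    cohort = vg.generate_cohort(spec, seed=7)
    result = vg.compute_grs(cohort, vg.GrsConfig(cohort.panel))
    rng = np.random.default_rng(77)
    high = result.scores >= 3.0
    p0 = 0.03
    p1 = 1 / (1 + np.exp(-(np.log(p0 / (1 - p0)) + 1.0)))
    df = cohort.data
    df["vte"] = np.where(high, rng.random(len(df)) < p1, rng.random(len(df)) < p0)
    so = vg.grs_stratified_or(cohort, result, low_band=(0, 1), high_cut=3.0)
    assert 2.3 <= so.odds_ratio.estimate <= 3.2
    assert so.n_excluded_midband > 0


def test_stratified_or_null_band_effect_near_one():
    spec = vg.GeneratorSpec()
    spec.n = {"roma": 50_000}
    cohort = vg.generate_cohort(spec, seed=8)
    result = vg.compute_grs(cohort, vg.GrsConfig(cohort.panel))
    so = vg.grs_stratified_or(cohort, result, low_band=(0, 1), high_cut=3.0)
    assert 0.75 <= so.odds_ratio.estimate <= 1.3


def test_stratified_or_zero_cases_high_band_haldane():
    spec = vg.GeneratorSpec()
    spec.n = {"roma": 4000}
    cohort = vg.generate_cohort(spec, seed=9)
    result = vg.compute_grs(cohort, vg.GrsConfig(cohort.panel))
    df = cohort.data
    df["vte"] = False
    low = (result.scores >= 0) & (result.scores <= 1)
    df.loc[df.index[low][:5], "vte"] = True  # cases only in the low band
    so = vg.grs_stratified_or(cohort, result, low_band=(0, 1), high_cut=3.0)
    assert so.separation_flag
    assert 0 < so.odds_ratio.estimate < 1
    assert so.odds_ratio.haldane_corrected


def test_env_joint_or_recovers_planted_effect():
    """Plant a log-OR of 1.2 for an exposure within the high-score stratum."""
    spec = vg.GeneratorSpec()
    spec.n = {"roma": 50_000}
    cohort = vg.generate_cohort(spec, seed=10)
    result = vg.compute_grs(cohort, vg.GrsConfig(cohort.panel))
    rng = np.random.default_rng(11)
    df = cohort.data
    e = df["migraine"].astype(bool).to_numpy()
    lp = np.log(0.03 / 0.97) + 1.2 * e
    df["vte"] = rng.random(len(df)) < 1 / (1 + np.exp(-lp))
    so = vg.grs_env_joint_or(cohort, result, "migraine", high_cut=3.0)
    assert abs(np.log(so.odds_ratio.estimate) - 1.2) <= 0.15


def test_env_joint_or_null_ci_coverage():
    """With no environmental effect planted the Wald CI covers OR = 1 in at
    least 90% of replicates."""
    spec = vg.GeneratorSpec()
    spec.n = {"roma": 3000}
    spec.outcome.intercept["roma"] = np.log(0.08 / 0.92)  # richer case count
    covered = 0
    reps = 100
    for r in range(reps):
        cohort = vg.generate_cohort(spec, seed=1000 + r)
        result = vg.compute_grs(cohort, vg.GrsConfig(cohort.panel))
        so = vg.grs_env_joint_or(cohort, result, "current_smoker", high_cut=3.0)
        covered += so.odds_ratio.ci_low <= 1.0 <= so.odds_ratio.ci_high
    assert covered / reps >= 0.90


def test_env_joint_or_constant_flag_errors(study_fixture):
    result = vg.compute_grs(study_fixture, vg.GrsConfig(study_fixture.panel))
    from vte_gxe.errors import DegenerateDataError
    with pytest.raises(DegenerateDataError):
        vg.grs_env_joint_or(study_fixture, result, "cancer", high_cut=3.0)
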