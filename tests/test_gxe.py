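"""Gene-environment machinery: rank-based normalisation, interaction designs,
the linear-probability fit, stratum ORs, and scale-specific verdicts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import vte_gxe as vg
from vte_gxe.errors import DegenerateDataError
from vte_gxe.gxe import InteractionDesign, binarize_exposure


# -- two-step inverse-normal transform --------------------------------------


def test_templeton_middle_maps_to_mean():
    out = vg.templeton_transform([1.0, 2.0, 3.0, 4.0, 5.0])
    assert out[2] == pytest.approx(3.0)


def test_templeton_preserves_rank_order_and_moments():
    rng = np.random.default_rng(5)
    x = rng.lognormal(0.0, 1.0, 2000)
    out = vg.templeton_transform(x)
    assert np.array_equal(np.argsort(out), np.argsort(x))
    assert out.mean() == pytest.approx(x.mean(), rel=1e-9)
    assert out.std(ddof=1) == pytest.approx(x.std(ddof=1), rel=1e-9)


def test_templeton_removes_lognormal_skew():
    """Post-transform skewness matches that of exact normal quantiles at the
    same ranks (which is ~0)."""
    rng = np.random.default_rng(6)
    x = rng.lognormal(0.0, 1.0, 10_000)
    out = vg.templeton_transform(x)
    n = x.size
    oracle = stats.norm.ppf((np.arange(1, n + 1) - 0.5) / n)
    assert abs(stats.skew(out)) < 0.05
    assert stats.skew(out) == pytest.approx(stats.skew(oracle), abs=1e-6)


def test_templeton_constant_vector_errors():
    with pytest.raises(DegenerateDataError):
        vg.templeton_transform(np.ones(10))


# -- design construction ----------------------------------------------------


def test_interaction_product_column(small_cohort):
    d = vg.build_interaction_design(small_cohort, "rs2066865", "migraine")
    assert np.array_equal(d.X["GxE"].to_numpy(),
                          d.X["G"].to_numpy() * d.X["E"].to_numpy())


def test_ldl_dichotomised_at_clinical_cut():
    df = pd.DataFrame({"ldl_c": [3.0, 3.4, 4.0]})
    assert binarize_exposure(df, "ldl_c").tolist() == [0.0, 1.0, 1.0]


@pytest.mark.parametrize("exposure,values,expected", [
    ("tc", [5.1, 5.2], [0.0, 1.0]),
    ("hdl_c", [1.2, 1.3], [1.0, 0.0]),
    ("tg", [1.6, 1.7], [0.0, 1.0]),
    ("bmi", [30.0, 30.1], [0.0, 1.0]),
])
def test_exposure_cut_directions(exposure, values, expected):
    assert binarize_exposure(pd.DataFrame({exposure: values}), exposure).tolist() == expected


def test_dominant_coding(small_cohort):
    d = vg.build_interaction_design(small_cohort, "rs2036914", "migraine",
                                    genetic_coding="dominant")
    assert set(np.unique(d.X["G"])) <= {0.0, 1.0}


def test_single_level_exposure_errors(study_fixture):
    with pytest.raises(DegenerateDataError):
        vg.build_interaction_design(study_fixture, "rs2066865", "cancer")


# -- linear-probability interaction fit -------------------------------------


def test_beta_std_equals_raw_on_standardized_data():
    rng = np.random.default_rng(3)
    x = rng.normal(size=500)
    x = (x - x.mean()) / x.std(ddof=1)
    y = 0.4 * x + rng.normal(size=500)
    y = (y - y.mean()) / y.std(ddof=1)
    fit = vg.fit_gxe_linear(pd.DataFrame({"GxE": x}), y)
    assert fit.beta_std["GxE"] == pytest.approx(fit.beta["GxE"], rel=1e-12)


def test_saturated_binary_fit_reproduces_cell_prevalences():
    rng = np.random.default_rng(4)
    n = 4000
    G = rng.binomial(1, 0.4, n).astype(float)
    E = rng.binomial(1, 0.3, n).astype(float)
    p = 0.05 + 0.04 * G + 0.03 * E + 0.05 * G * E
    y = (rng.random(n) < p).astype(float)
    fit = vg.fit_gxe_linear(pd.DataFrame({"G": G, "E": E, "GxE": G * E}), y)
    for g in (0, 1):
        for e in (0, 1):
            m = (G == g) & (E == e)
            assert fit.fitted[m][0] == pytest.approx(y[m].mean(), abs=1e-10)


def test_rank_deficient_design_errors():
    x = np.arange(50, dtype=float)
    X = pd.DataFrame({"G": x, "E": 2 * x, "GxE": x})
    with pytest.raises(DegenerateDataError, match="collinear"):
        vg.fit_gxe_linear(X, np.r_[np.zeros(25), np.ones(25)])


def test_interaction_sign_recovered_with_planted_excess_risk():
    """A planted positive interaction yields a positive standardized G x E
    coefficient in at least 95% of replicates."""
    hits = 0
    reps = 100
    for r in range(reps):
        rng = np.random.default_rng(50_000 + r)
        n = 5000
        G = rng.binomial(2, 0.28, n).astype(float)
        E = rng.binomial(1, 0.25, n).astype(float)
        lp = np.log(0.02 / 0.98) + 0.2 * G + 0.3 * E + 1.0 * G * E
        y = (rng.random(n) < 1 / (1 + np.exp(-lp))).astype(float)
        fit = vg.fit_gxe_linear(pd.DataFrame({"G": G, "E": E, "GxE": G * E}), y)
        hits += fit.beta_std_interaction > 0
    assert hits / reps >= 0.95


# -- stratum ORs and verdicts -----------------------------------------------


def test_stratum_or_exact_cross_products():
    s = vg.stratum_ors_from_cells({(0, 0): (2, 100), (1, 0): (4, 100),
                                   (0, 1): (4, 100), (1, 1): (16, 100)})
    assert (s.or01, s.or10, s.or11) == (2.0, 2.0, 8.0)
    assert s.reri == pytest.approx(8 - 2 - 2 + 1)


def test_stratum_or_identical_prevalence_all_one():
    s = vg.stratum_ors_from_cells({k: (5, 95) for k in [(0, 0), (1, 0), (0, 1), (1, 1)]})
    assert s.or01 == s.or10 == s.or11 == 1.0


def test_stratum_or_empty_cell_flagged():
    s = vg.stratum_ors_from_cells({(0, 0): (2, 100), (1, 0): (0, 0),
                                   (0, 1): (4, 100), (1, 1): (3, 50)})
    assert s.incomplete and np.isnan(s.or01)


def test_reri_identity_property():
    rng = np.random.default_rng(12)
    for _ in range(50):
        cells = {k: (int(rng.integers(1, 40)), int(rng.integers(1, 200)))
                 for k in [(0, 0), (1, 0), (0, 1), (1, 1)]}
        s = vg.stratum_ors_from_cells(cells)
        assert s.reri == pytest.approx(s.or11 - s.or01 - s.or10 + 1.0, rel=1e-12)


# all nine (multiplicative x additive) verdict combinations:
# multiplicative null = OR01*OR10, additive null = OR01 + OR10 - 1
@pytest.mark.parametrize("or01,or10,or11,mult,add", [
    (1.0, 2.0, 2.0, "none", "none"),            # OR11 equals both nulls
    (2.0, 3.0, 6.0, "none", "synergistic"),     # at mult null, RERI = 2
    (0.5, 3.0, 1.5, "none", "antagonistic"),    # at mult null, RERI = -1
    (0.5, 3.0, 2.5, "synergistic", "none"),     # at additive null, above mult
    (2.0, 3.0, 8.0, "synergistic", "synergistic"),
    (0.5, 3.0, 2.0, "synergistic", "antagonistic"),
    (2.0, 3.0, 4.0, "antagonistic", "none"),    # at additive null, below mult
    (2.0, 3.0, 5.0, "antagonistic", "synergistic"),
    (2.0, 3.0, 3.5, "antagonistic", "antagonistic"),
])
def test_interaction_verdict_truth_table(or01, or10, or11, mult, add):
    s = vg.StratumOrSet(1.0, or01, or10, or11, {})
    v = vg.classify_interaction(s)
    assert v.multiplicative == mult
    assert v.additive == add
    assert v.reri == pytest.approx(or11 - or01 - or10 + 1.0)


def test_verdicts_invariant_to_swapping_g_and_e():
    cells = {(0, 0): (3, 120), (1, 0): (6, 110), (0, 1): (9, 100), (1, 1): (30, 80)}
    swapped = {(g, e): cells[(e, g)] for g, e in cells}
    v1 = vg.classify_interaction(vg.stratum_ors_from_cells(cells))
    v2 = vg.classify_interaction(vg.stratum_ors_from_cells(swapped))
    assert (v1.multiplicative, v1.additive) == (v2.multiplicative, v2.additive)
    assert v1.reri == pytest.approx(v2.reri)


def test_multiplicative_null_model_converges_to_no_interaction():
    """Data generated under a log-linear (multiplicative-null) outcome model:
    OR11/(OR01*OR10) -> 1, while positive main effects force RERI > 0 — the
    scale-dependence the framework encodes."""
    rng = np.random.default_rng(13)
    n = 200_000
    G = rng.binomial(1, 0.4, n)
    E = rng.binomial(1, 0.3, n)
    lp = np.log(0.01 / 0.99) + 0.8 * G + 0.9 * E
    y = rng.random(n) < 1 / (1 + np.exp(-lp))
    cells = {(g, e): (int(y[(G == g) & (E == e)].sum()),
                      int((~y[(G == g) & (E == e)]).sum()))
             for g in (0, 1) for e in (0, 1)}
    s = vg.stratum_ors_from_cells(cells)
    assert abs(s.or11 / (s.or01 * s.or10) - 1.0) <= 0.1
    assert s.reri > 0


def test_null_interaction_p_uniformity_small():
    """Quick calibration check of the interaction p-value under the fully
    null generator (the acceptance suite runs the full-size version)."""
    rej = 0
    reps = 200
    for r in range(reps):
        rng = np.random.default_rng(90_000 + r)
        n = 2000
        G = rng.binomial(2, 0.3, n).astype(float)
        E = rng.binomial(1, 0.3, n).astype(float)
        y = (rng.random(n) < 0.05).astype(float)
        fit = vg.fit_gxe_linear(pd.DataFrame({"G": G, "E": E, "GxE": G * E}), y)
        rej += fit.p_interaction < 0.05
    assert 0.02 <= rej / reps <= 0.09


def test_bootstrap_ci_covers_point_estimate(small_cohort):
    df = small_cohort.data
    rng = np.random.default_rng(14)
    df["vte"] = rng.random(len(df)) < 0.08  # enough cases for stable cells
    cohort = vg.CohortTable(df, small_cohort.panel)
    boot = vg.bootstrap_interaction_ci(cohort, "rs2036914", "current_smoker",
                                       n_resamples=300, seed=15)
    s = vg.stratum_ors(cohort, "rs2036914", "current_smoker")
    v = vg.classify_interaction(s)
    lo, hi = boot.mult_excess_ci
    assert lo <= v.multiplicative_excess <= hi
    assert boot.n_resamples == 300


def test_bootstrap_deterministic_given_seed(small_cohort):
    df = small_cohort.data
    rng = np.random.default_rng(16)
    df["vte"] = rng.random(len(df)) < 0.08
    cohort = vg.CohortTable(df, small_cohort.panel)
    b1 = vg.bootstrap_interaction_ci(cohort, "rs2036914", "current_smoker",
                                     n_resamples=100, seed=99)
    b2 = vg.bootstrap_interaction_ci(cohort, "rs2036914", "current_smoker",
                                     n_resamples=100, seed=99)
    assert b1.mult_excess_ci == b2.mult_excess_ci
    assert b1.reri_ci == b2.reri_ci


def test_interaction_analysis_end_to_end(small_cohort):
    r = vg.interaction_analysis(small_cohort, "rs2066865", "current_smoker",
                                population="roma")
    assert r.verdict.multiplicative in {"none", "synergistic", "antagonistic"}
    assert np.isfinite(r.stratum_ors.or11) or r.stratum_ors.incomplete
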