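# Methods

## Data model

A cohort is one row per subject: population (`general` / `roma`), sex, age
(years, validated to the survey's 20–64 range), quantitative covariates
(BMI kg/m², waist circumference cm; total, LDL and HDL cholesterol,
triglycerides and fasting glucose in mmol/L), binary condition flags
(cancer, diabetes, coronary artery disease, chronic kidney disease,
migraine, depression, smoking categories, obesity), the binary VTE outcome,
and per-SNP genotypes.  Genotypes are normalised on ingestion to
*risk-allele dosage* (0/1/2) from any of three dialects — "G/A", "GA", or an
integer — and missing values are excluded pairwise (per SNP) from allele
counts and per-analysis from regressions, with exclusion counts reported.
SNPs are identified by rsID only; no genomic coordinates are stored because
no computation uses them.

The rs8176719 indel is modelled with abstract alleles `C`/`DEL`.  The
published frequency of the risk allele (0.47/0.48) is numerically
consistent only with the deletion-bearing genotype counts, so `DEL` is the
default risk allele; the orientation is configurable in the SNP panel YAML.

## Population-genetic tests

**Allele frequency** is (n_het + 2·n_hom_risk)/(2·n_typed) over typed
subjects, cases and non-cases combined (the published stratum totals match
that reading).

**Hardy–Weinberg** uses the conditional exact test: holding the observed
allele counts fixed, the two-sided p-value sums the probabilities of all
heterozygote counts whose conditional probability does not exceed the
observed one.  Probabilities are computed with log-gamma arithmetic; a
relative slack of 1e-12 guards the ≤ comparison against floating-point
ties.  A monomorphic stratum has a single attainable configuration and
returns p = 1.  The test suite checks this implementation against an
independent exact-rational enumeration (big-integer combinatorics) to
1e-12 across random counts up to n = 500.

**The allelic test** is Pearson's χ² (1 df, *no* continuity correction) on
the 2×2 allele-count table — the uncorrected statistic is what reproduces
the published p-values (F2 0.037 → 0.04, FGG 0.054 → 0.05) from the count
tables.  Whenever an expected cell is below 5, a two-sided Fisher exact
p-value is computed alongside and used for the Bonferroni verdict.
Bonferroni control is α/m with m the panel size (0.05/6 = 0.0083).
Reported p-values are rounded to two significant figures in text reports;
full precision is kept internally.

## Association and separation

Crude per-genotype ORs are cross-products against the non-risk homozygote,
with Woolf (log-scale Wald) 95% CIs.  Any zero cell triggers the
Haldane–Anscombe correction (0.5 added to all four cells) and a flag; the
corrected OR is finite and positive for every table.  Note the correction
can pull a zero-case OR *above* 1 when the reference odds are very low —
the flag, not the point value, is the interpretable output in that case.

Age-adjusted ORs come from maximum-likelihood logistic regression
(iteratively reweighted least squares via statsmodels GLM).  Constant
columns are dropped and reported.  Separation is declared when any slope
exceeds 15 on the log-odds scale, or the outcome is degenerate; separated
genotype rows are reported with the flag plus the corrected crude OR
instead of a pseudo-converged estimate.  A compatibility option also prints
the diverged point estimate (→ 0 for zero-case strata) for display parity
with legacy outputs.  Age enters linearly in years.  Firth or Bayesian
rare-event corrections are deliberately out of scope.

## Genetic risk scores

Coded dosage is the raw dosage, or 2 − dosage for a SNP whose nominal risk
allele behaves protectively (`flip`).  uGRS sums coded dosages (integer,
0–2m); wGRS is the weight-dosage inner product with weights = ln OR from an
external discovery study.  Those external ORs were never published for this
panel, so the bundled weights are *plausible-magnitude placeholders*,
clearly marked in `reference.py`, editable via the YAML panel config, and
never asserted as ground truth — all weighted-score tests are
property-based (orientation invariance, bounds, arithmetic).  The founder
SNP carries no weight and is excluded from the weighted score.

Dichotomisation: default explicit bands — high ≥ 3, low 0–1 — with the
middle band excluded and its size reported; a median rule is also
available, with ties assigned to the high group (a "≥ median" reading).
Subjects missing any panel dosage are excluded from scores, not imputed.

## Gene–environment interaction

Continuous exposures are dichotomised at clinical cut-offs: TC ≥ 5.2,
LDL-C ≥ 3.4, HDL-C < 1.3, TG ≥ 1.7 mmol/L, BMI > 30 kg/m².  Skewed
biomarkers can first be normalised by the two-step transform: fractional
rank (ties averaged) mapped to (rank − 0.5)/n, inverse standard-normal
quantile, then a linear rescale so the output's sample mean and SD equal
the input's exactly.  The transform is monotone and leaves rank order
unchanged.

The regression is a linear-probability OLS of the 0/1 outcome on G (dosage
coding by default), E, G×E and age, reported as standardized coefficients
β·SD(x)/SD(y) with two-sided t p-values — the formulation that matches how
such interaction betas are conventionally reported from general-purpose
statistical packages.  Because the Bernoulli variance differs across (G,E)
cells whenever main effects are present, the classical t-test on the
product term is anti-conservative in that regime; `robust=True` substitutes
HC3 heteroskedasticity-consistent standard errors for analyses where that
matters.  The default stays classical for fidelity to the plain-linear-
regression convention; the null-calibration properties quoted by the test
suite are computed under the fully null generator, where the classical test
is exact.  A logistic mirror of any fit is available through
`fit_logistic` for sensitivity analysis.

Stratum ORs binarise G as carrier/non-carrier (dominant) by default —
configurable to recessive — and compare the genetic-only (0,1), environment-
only (1,0) and joint (1,1) cells against the doubly unexposed cell by
cross-products, Haldane-corrected per contrast when needed.  Verdicts:
multiplicative synergy/antagonism from the sign of OR₁₁ − OR₀₁·OR₁₀,
additive from the sign of RERI = OR₁₁ − OR₀₁ − OR₁₀ + 1, each within a
configurable relative tolerance band (default 0 → point verdicts).  These
verdicts are scale-dependent by construction: a purely log-linear
(multiplicative-null) risk model with positive main effects is
additive-synergistic in the limit, and the suite asserts exactly that.
Because point verdicts at n ≈ 400 with ~18 outcome events are
noise-dominated, a subject-level bootstrap (seeded, default 2,000
resamples) provides percentile CIs for both contrasts and a CI-aware
verdict that returns "none" when the interval covers zero.

Combined-population models add an ethnicity main effect; per-population
stratified fits are the primary report.  Each (SNP, exposure) pair is
fitted in its own model (one interaction term at a time, plus age).  No
multiple-testing adjustment is applied across the interaction grid in the
primary output; `p_interaction` is exposed so Benjamini–Hochberg can be
applied downstream.

## Synthetic cohorts

The generator's defaults *are* the study conditions: 406 general / 395 Roma
subjects; risk-allele frequencies 0/0.01 (founder SNP), 0.02/0.01, 0.54/
0.51, 0.23/0.28, 0.07/0.09, 0.47/0.48; covariate means from the published
summaries with SDs backed out of the printed 95% CIs (SD = half-width·√N/
1.96); female fractions 55.4% / 73.9%; baseline VTE prevalence 1.5% / 3.0%.
Genotypes are Binomial(2, p) per SNP — Hardy–Weinberg, no linkage
disequilibrium (a known simplification; the analysis treats SNPs
marginally).  Triglycerides are log-normal (moment-matched) by default so
the normalisation step is exercised on realistic right skew.  Condition
prevalences were not published; the bundled values are nominal
survey-plausible figures and are labelled as such.  Conditions are drawn
independently of genotypes unless an outcome coefficient links them —
exposures, not mediators.  Obesity derives from simulated BMI > 30 rather
than an independent draw, keeping the flag coherent with the biomarker.

The outcome is Bernoulli(inverse-logit) of an intercept (per population)
plus configurable log-odds for dosages, exposures, products and centred
age.  Generation is bit-reproducible given spec + seed.

A second, deterministic constructor rebuilds a cohort whose per-SNP
genotype × outcome × population counts equal the published tables exactly
(cases first, genotypes assigned blockwise and independently per SNP;
covariates at population means).  It supports count-level analyses only:
the joint genotype distribution across SNPs, and all covariate variation,
are synthetic conveniences.

## What the tests do and do not show

Passing tests demonstrate: exact reproduction of the published count-level
quantities (frequencies, allelic p-values, prevalences, crude ORs);
agreement of the exact HWE test with an independent enumeration; internal
consistency (logistic ⇔ cross-product, orientation invariance, verdict
truth table); and parameter recovery from the generator at N = 50,000–
200,000 (allele frequencies within ±0.005, main-effect and interaction
log-odds within ±0.1, interaction-test size within [0.03, 0.07] over 1,000
null replicates at N = 5,000 — sizes chosen to keep the whole suite to a
few minutes on one core).  They do *not* validate the published
age-adjusted ORs, standardized interaction betas, or score means/ranges:
those depend on individual-level ages, covariates and unpublished external
weights that were never deposited, so no test asserts them.  Real cohorts
additionally carry linkage disequilibrium, genotype-covariate correlation
and informative missingness that the generator does not emulate.

## Numerical choices

* Woolf CI z = 1.95996…; Haldane 0.5 on any zero cell, always flagged.
* Separation bound 15 on the log-odds scale; GLM maxiter 200.
* HWE float-tie slack 1e-12 (relative).
* Transform percentile (rank − 0.5)/n — symmetric, keeps extremes finite.
* Median-cut ties go to the high-score group.
* Bootstrap resamples drawn subject-level with a `numpy` Generator seeded
  per analysis; degenerate resamples (an empty joint cell) are dropped and
  counted.
* Report p-values rounded to 2 significant figures; internal precision full.
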