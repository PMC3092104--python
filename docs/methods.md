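# Methods

This note documents the statistical models implemented in `psymetab`, the
assumptions of the synthetic-data generator, the numerical choices made
where the design was genuinely open, and what the test suite does and
does not establish.

## Synthetic cohort and feature generator

**Design.** Three diagnostic strata — schizophrenia (45 cases), other
non-affective psychoses (57) and affective psychoses (37) — each matched
1:1 to controls on age and sex (shared within pair).  Covariates are drawn
per (stratum, role): right-skewed biomarkers (insulin, triglycerides, CRP,
cotinine, GGT, alcohol) are log-normal with moments matched to published
group means/SDs; approximately symmetric ones (age, blood pressure, BMI,
cholesterol fractions, fasting time, BDI) are truncated normal.  HOMA-IR
is derived as insulin[μIU/ml] × glucose[mg/dl] / 405 (the standard
formula, consistent in magnitude with the published group means); LDL is
the Friedewald estimate; obesity is BMI ≥ 30; metabolic comorbidity is
the OR-composite of type 2 diabetes, metabolic syndrome and obesity.

**Features.** Each platform's features are organized in latent clusters
(lipid: 13 clusters with sizes 112, 48, 11, 15, 31, 21, 20, 34, 17, 21,
9, 7, 5, totaling 351; polar: 34, 18, 10, 53, 38, 25, 17, 6, totaling
201).  A per-subject latent score per cluster is the sum of a shared
per-pair intercept (SD 0.5), the planted shifts, and unit-SD Gaussian
noise.  A member feature's log concentration is

    log x = baseline + s · (λ · z + √(1−ρ) · η),

where z is the standardized latent, λ = √ρ with ρ = 0.8 the within-cluster
log-scale correlation, η feature noise, and s = 0.35 the log-signal
amplitude (a realistic ~35–40 % concentration CV).  Concentrations are
therefore strictly positive and log-normal.  Two scalar choices matter and
were made on first principles:

- *Log-signal amplitude 0.35.*  With unit log-SD the exponential map is so
  nonlinear that the standardized raw profile of a large cluster becomes a
  curved manifold, which a Gaussian mixture legitimately splits; at
  realistic CVs the standardized profiles are near-linear in the latent
  and the planted clusters are genuinely Gaussian blobs.  Because
  downstream modeling is on the log scale, s rescales effects and
  residuals together and leaves t statistics unchanged.
- *Effect magnitudes.*  The emulated study reports only signs and t
  statistics, not effect sizes.  Diagnosis and comorbidity shifts default
  to 1.0–1.2 latent SD — large enough that a matched design with 37–57
  pairs per stratum detects each with high power, small enough that
  single-marker discrimination is imperfect (cross-validated AUC ≈ 0.8).
  Diet, medication and fasting effects are 0.4–0.6 SD.

**Markers.**  The diagnostic panel emulates the study's hierarchy: the
proline analogue loads strongly on its cluster (1.2× the common loading),
the triglyceride analogue moderately (0.8×), and the isoleucine analogue
tracks its cluster's baseline co-regulation at full loading but responds
to the planted shifts with attenuation 0.15 (not every member of a
co-regulated group shifts equally with disease).  Insulin is coupled to
the LC9/MC5 latents (0.3 SD per SD of insulin), which reproduces the
expected dependency-network structure (insulin–LC9–MC5) and makes insulin
largely redundant as a marker once the cluster markers are in the model.

**What the generator does not emulate:** measurement batch effects,
missing or censored peaks, platform drift, nonlinear covariate-metabolite
relationships, and metabolite-level identities beyond the designated
marker analogues.  Passing recovery tests therefore show that the methods
are implemented correctly and behave as designed under the stated
generative assumptions, not that they would perform identically on real
spectra-derived data.

## Feature clustering

Observations are metabolites; each observation vector is the feature's
profile across subjects, scaled to mean 0 / unit variance (sample SD,
ddof = 1, so the profile (2, 4, 6) maps exactly to (−1, 0, 1)).  EM fits
mixtures for K = 4..15 by default under four covariance
parameterizations — spherical or diagonal, equal or varying across
components; full-covariance families are accepted only when the dimension
is below the observation count, which it is not at this design's scale.
Model selection maximizes BIC = 2ℓ̂ − m ln N (higher is better).

Numerical choices: k-means++ initialization with 5 restarts, the first
replaced by a deterministic Ward agglomerative start (hierarchical
initialization is markedly better at isolating small tight clusters, e.g.
the 5-feature lipid cluster); convergence at relative log-likelihood
change < 1e-6 or 500 iterations; a variance floor of 1e-3 of the data's
mean per-dimension variance (without it, singleton components collapse
onto single points and dominate the likelihood); empty components trigger
a restart and, failing all restarts, a flagged non-converged fit.  The
log-likelihood trace is retained and is non-decreasing (asserted in
tests).

Cluster scores for downstream modeling are the arithmetic mean of member
features' raw concentrations (means of z-scores can be negative and
cannot be logged); the natural log of the score is the modeling response,
and mean standardized profiles are exposed separately for plotting.

## Descriptive statistics

χ² is the uncorrected Pearson statistic on 2×2 counts with df = 1 — the
convention that reproduces the published p = 0.020 for the
type-2-diabetes counts (11/34 vs 3/42) and p = 0.024 for the metabolic
comorbidity counts (33/24 vs 21/36).  Mann-Whitney U uses exact
enumeration for combined samples ≤ 12 without ties and the tie-corrected
normal approximation with continuity correction otherwise (verified
within 0.02 of exact at the boundary).  Per-cluster ANOVA operates on log
cluster scores across four groups (three case strata, controls pooled),
with significance stars at 0.05/0.001.  No multiple-testing correction is
applied, matching the per-cluster reporting convention of the emulated
analysis.

## Matched-pair linear mixed models

Per cluster: y = Xβ + b_pair + ε with b ~ N(0, σ²_pair),
ε ~ N(0, σ²_resid); y is the natural-log cluster score; X contains an
intercept, the three diagnosis indicators (pooled controls as baseline,
all strata fitted jointly), current antipsychotic use, metabolic
comorbidity, four diet flags and fasting time.  Sex and age are excluded
(the matching already balances them).  Estimation profiles the variance
ratio θ = σ²_pair/σ²_resid out of the REML objective — exact here because
each pair's covariance block is I + θJ with closed-form inverse and
determinant — and optimizes θ by bounded scalar search (θ = 0 is an
admissible boundary solution).  The implementation is cross-checked
against statsmodels' MixedLM in the test suite.

t statistics use containment-style residual degrees of freedom
df = n_obs − rank(X) − n_pairs + 1 (for a balanced paired design with a
single indicator this equals the paired-t df, and the t statistic matches
the paired t-test to 1e-6; the df method is configurable).  Missing rows
are dropped per fit (complete case) with the count logged.  The
sensitivity refit drops every pair in which either member has type 2
diabetes and reruns all clusters.

## NRR dependency network

Variables: 21 cluster log-scores, 4 diagnosis indicators (three strata
plus NIDDM), and 27 phenotype/lifestyle variables (p = 52; binary
variables enter as numeric 0/1, a deliberate simplification within the
Gaussian framework).  For each pair (i, j), the partial correlation given
a conditioning set Q is computed from the inverse of the covariance
submatrix over {i, j} ∪ Q (pseudo-inverse with tolerance if singular; a
submatrix singular beyond tolerance counts as a rejection).  The test
statistic is t = r·√((n−q−2)/(1−r²)) against t_{n−q−2}, at per-test level
α = 0.05 (α is not stated in the emulated analysis; it is configurable).
Per q ∈ {1, 13, 26, 38} (the canonical grid for p = 52; otherwise evenly
spread over [1, p−3]), 500 conditioning subsets are sampled uniformly —
read as 500 subsets *per q level*, i.e. 2,000 tests per pair; exhaustive
enumeration replaces sampling whenever C(p−2, q) ≤ 500.  The NRR is the
fraction of non-rejections over all tests, and edges satisfy NRR ≤ β
with β = 0.25.

Per-pair random streams are keyed by the unordered variable-name pair and
conditioning candidates are drawn from the name-sorted list, so results
are invariant to column reordering.  Under global independence the mean
NRR over pairs and replicate datasets is ≈ 1 − α (single-dataset means
fluctuate beyond binomial error because all pairs share one estimated
covariance matrix — the calibration test averages over replicates for
this reason).

## Diagnostic cross-validation

Labels: schizophrenia (45) vs pooled other psychoses (94); controls are
excluded.  Markers are log-transformed and standardized (concentrations
are log-normal; raw mode available).  Each of the n_runs iterations draws
a simple random (unstratified) 93/46 split, runs bidirectional stepwise
selection from the intercept-only model — at each step the single add or
drop move that most decreases AIC = −2ℓ̂ + 2k, ties broken by marker-name
order — and evaluates the selected model on the held-out set: ROC AUC
(concordant pairs + half ties), and OR/RR of the dichotomized
classification at probability cutoff 0.5 with the Haldane–Anscombe +0.5
correction applied to all cells whenever any cell is zero.  Logistic fits
use IRLS (tolerance 1e-8, max 100 iterations) via statsmodels GLM;
quasi-separation is flagged when any standardized coefficient exceeds 15.
Splits whose test set lacks a class are resampled and counted.

Because a single 139-subject cohort realization carries sampling noise of
roughly ±0.18 SD in each marker's observed class separation, the *modal*
selected subset of one cohort is not a stable quantity; marker-recovery
checks therefore pool selection counts over replicate cohorts, under
which the planted TG + proline pair is modal with the expected runner-up
hierarchy (adding insulin or isoleucine, proline alone).

## Pipeline

Stages run in the order simulate → cluster → stats → lmm → network →
diagnose; each stage's seed is derived by hashing (master seed, stage
name), so toggling one stage does not shift another's random stream.  The
manifest records parameters, seeds and SHA-256 checksums of every output;
reruns with the same config and seed are bit-identical.  All tabular
outputs are UTF-8 CSV with a header row.

## Problem sizes used in tests and the acceptance script

Cluster-recovery runs use 30 matched pairs (60 subjects, the "reduced
dimension") and 10 replicate seeds per platform; the CV marker check
pools 5 replicate cohorts × 200 runs; LMM recovery uses 25–50 simulated
139-pair datasets; NRR calibration uses n = 200 with 2,000 tests per pair
over 45 pairs × 5 replicates.  These sizes were chosen so each check's
Monte-Carlo error is small relative to its assertion band.

## Known limitations

- Full-covariance mixture families delegate to scikit-learn's EM and are
  only available when dimension < observations; the per-iteration
  likelihood trace is not exposed for them.
- The mixed model supports a single random intercept (the matched pair);
  crossed or nested designs are out of scope.
- The NRR network treats binary variables as Gaussian; no causal
  orientation or layout is attempted.
- OR/RR derive from dichotomized predictions at a fixed cutoff; the
  per-unit-coefficient alternative is not implemented.
- The generator's 360-vs-351 lipid-count discrepancy in the emulated
  study is resolved in favor of the per-cluster sizes (sum 351); the
  total is configurable.
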