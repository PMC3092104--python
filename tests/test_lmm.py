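"""Matched-pair mixed model: OLS/paired-t equivalences, REML behavior,
parameter recovery, variance attribution, sensitivity refit."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import psymetab as pm
from psymetab.lmm import fit_lmm_arrays, reml_profile


def _paired_design(n_pairs, rng, beta=0.4, pair_sd=0.7, resid_sd=1.0):
    pairs = np.repeat(np.arange(n_pairs), 2)
    case = np.tile([1.0, 0.0], n_pairs)
    X = np.column_stack([np.ones(2 * n_pairs), case])
    y = (beta * case + pair_sd * np.repeat(rng.normal(size=n_pairs), 2)
         + resid_sd * rng.normal(size=2 * n_pairs))
    return y, X, pairs


class TestEstimation:
    def test_no_pair_variance_reduces_to_ols(self, rng):
        y, X, pairs = _paired_design(40, rng, pair_sd=0.0)
        fit = fit_lmm_arrays(y, X, pairs, ["intercept", "case"])
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        np.testing.assert_allclose(fit.beta, ols, atol=1e-6)

    def test_paired_t_equivalence(self, rng):
        """With a balanced paired design the case-effect t equals the
        paired t-test on case-minus-control differences."""
        y, X, pairs = _paired_design(35, rng)
        fit = fit_lmm_arrays(y, X, pairs, ["intercept", "case"])
        diffs = y[::2] - y[1::2]
        t_ref = sps.ttest_rel(y[::2], y[1::2])
        assert fit.t[1] == pytest.approx(t_ref.statistic, abs=1e-6)
        assert fit.df == 34
        assert fit.p[1] == pytest.approx(t_ref.pvalue, abs=1e-6)

    def test_pure_pair_effects(self, rng):
        """Cases identical to controls plus pair offsets: residual variance
        collapses and the case effect vanishes."""
        n = 30
        pairs = np.repeat(np.arange(n), 2)
        case = np.tile([1.0, 0.0], n)
        y = np.repeat(rng.normal(size=n), 2)
        X = np.column_stack([np.ones(2 * n), case])
        fit = fit_lmm_arrays(y, X, pairs, ["intercept", "case"])
        assert fit.sigma2_resid < 1e-3 * fit.sigma2_pair
        assert abs(fit.t[1]) < 1e-3

    def test_scale_equivariance(self, rng):
        y, X, pairs = _paired_design(40, rng)
        a = fit_lmm_arrays(y, X, pairs, ["intercept", "case"])
        b = fit_lmm_arrays(3.0 * y, X, pairs, ["intercept", "case"])
        assert b.sigma2_resid == pytest.approx(9 * a.sigma2_resid, rel=1e-4)
        assert b.sigma2_pair == pytest.approx(9 * a.sigma2_pair, rel=1e-4, abs=1e-8)
        np.testing.assert_allclose(b.t, a.t, rtol=1e-6)

    def test_log_base_invariance(self, rng):
        y, X, pairs = _paired_design(40, rng)
        a = fit_lmm_arrays(y, X, pairs, ["intercept", "case"])
        b = fit_lmm_arrays(y / np.log(10), X, pairs, ["intercept", "case"])
        np.testing.assert_allclose(b.t, a.t, rtol=1e-6)
        np.testing.assert_allclose(b.p, a.p, rtol=1e-6)

    def test_rank_deficiency_names_aliased(self, rng):
        y, X, pairs = _paired_design(20, rng)
        X2 = np.column_stack([X, X[:, 1]])
        with pytest.raises(ValueError, match="dup"):
            fit_lmm_arrays(y, X2, pairs, ["intercept", "case", "dup"])

    def test_reml_optimum_is_global_on_grid(self, rng):
        y, X, pairs = _paired_design(40, rng, pair_sd=0.8)
        fit = fit_lmm_arrays(y, X, pairs, ["intercept", "case"])
        objective, _ = reml_profile(y, X, pairs)
        at_opt = objective(fit.theta)
        for theta in np.concatenate([[0.0], np.geomspace(1e-3, 100, 40)]):
            assert at_opt <= objective(theta) + 1e-6
        if fit.theta > 1e-6:  # interior optimum: flat gradient
            h = 1e-5 * (1 + fit.theta)
            grad = (objective(fit.theta + h) - objective(fit.theta - h)) / (2 * h)
            assert abs(grad) < 1e-4

    def test_statsmodels_cross_check(self, rng):
        """Independent oracle: REML estimates match statsmodels MixedLM."""
        import statsmodels.api as sm
        y, X, pairs = _paired_design(60, rng, beta=0.3, pair_sd=0.6)
        fit = fit_lmm_arrays(y, X, pairs, ["intercept", "case"])
        ref = sm.MixedLM(y, X, groups=pairs).fit(reml=True)
        np.testing.assert_allclose(fit.beta, ref.fe_params, rtol=1e-4)
        np.testing.assert_allclose(fit.se, ref.bse_fe, rtol=1e-3)
        assert fit.sigma2_pair == pytest.approx(
            float(np.asarray(ref.cov_re)[0, 0]), rel=2e-2, abs=1e-3)
        assert fit.sigma2_resid == pytest.approx(ref.scale, rel=2e-2)

    def test_parameter_recovery_and_coverage(self):
        """139-pair design with a known schizophrenia effect on the log
        scale: near-unbiased estimates and nominal CI coverage."""
        beta_true = 0.4
        estimates, covered = [], 0
        n_seeds = 50
        for seed in range(n_seeds):
            rng = np.random.default_rng(900 + seed)
            y, X, pairs = _paired_design(139, rng, beta=beta_true,
                                         pair_sd=0.5, resid_sd=1.0)
            fit = fit_lmm_arrays(y, X, pairs, ["intercept", "case"])
            estimates.append(fit.beta[1])
            half = sps.t.ppf(0.975, fit.df) * fit.se[1]
            covered += abs(fit.beta[1] - beta_true) <= half
        assert np.mean(estimates) == pytest.approx(beta_true, abs=0.05)
        assert 0.90 <= covered / n_seeds <= 0.99


class TestReports:
    def test_alpha_zero_reports_none(self, default_study, default_truth_scores):
        fits = pm.fit_all_clusters(default_study.cohort, default_truth_scores)
        rep = pm.lmm_report(fits, alpha=0.0)
        assert (rep.effect == "None").all()

    def test_null_false_positive_rate(self):
        """With no planted effects the expected number of flagged
        predictors per cluster is ~ alpha * n_effects."""
        counts = []
        for seed in range(8):
            cfg = pm.CohortConfig(group_sizes={"schizophrenia": 20, "onap": 20,
                                               "affective": 20},
                                  seed=700 + seed, effect_specs=[])
            coh = pm.generate_cohort(cfg)
            spec = pm.ClusterSpec(platform="polar", cluster_sizes=[8] * 5)
            study = pm.generate_features(coh, spec, effects=[], seed=700 + seed)
            scores = pm.cluster_scores(study.polar_features,
                                       study.truth["assignment"])
            rep = pm.lmm_report(pm.fit_all_clusters(coh, scores))
            flagged = rep[rep.effect != "None"]
            counts.append(len(flagged) / 5)
        n_effects = len(pm.LmmSpec().fixed_effects)
        expected = 0.05 * n_effects
        assert np.mean(counts) == pytest.approx(expected, abs=0.45)

    def test_planted_diagnosis_and_comorbidity_reported(self, default_study,
                                                        default_truth_scores):
        rep = pm.lmm_report(pm.fit_all_clusters(default_study.cohort,
                                                default_truth_scores))
        lc9 = rep[rep.cluster == "LC9"]
        assert {"schizophrenia", "metabolic_comorbidity"} <= set(lc9.effect)
        assert (lc9[lc9.effect.isin(["schizophrenia", "metabolic_comorbidity"])]
                .direction == "up").all()


class TestSensitivity:
    def test_noop_without_t2d(self, rng):
        cfg = pm.CohortConfig(group_sizes={"schizophrenia": 12, "onap": 12,
                                           "affective": 12}, seed=31)
        coh = pm.generate_cohort(cfg)
        coh["t2d"] = False
        coh = pm.derive_covariates(coh)
        spec = pm.ClusterSpec(platform="polar", cluster_sizes=[10, 10])
        study = pm.generate_features(coh, spec, effects=[], seed=31)
        scores = pm.cluster_scores(study.polar_features,
                                   study.truth["assignment"])
        full = pm.lmm_report(pm.fit_all_clusters(coh, scores))
        sens = pm.sensitivity_excluding_t2d(coh, scores)
        pd.testing.assert_frame_equal(full, sens)

    def test_pair_bookkeeping(self, default_study, default_truth_scores):
        coh = default_study.cohort
        sens = pm.sensitivity_excluding_t2d(coh, default_truth_scores)
        t2d_pairs = coh.loc[coh.t2d.astype(bool), "pair_id"].nunique()
        assert sens.attrs["n_pairs_excluded"] == t2d_pairs
        assert sens.attrs["n_pairs_retained"] == 139 - t2d_pairs

    def test_schizophrenia_effect_survives_exclusion(self, default_study,
                                                     default_truth_scores):
        sens = pm.sensitivity_excluding_t2d(default_study.cohort,
                                            default_truth_scores)
        lc9 = sens[(sens.cluster == "LC9") & (sens.effect == "schizophrenia")]
        assert len(lc9) == 1 and lc9.direction.iloc[0] == "up"


def test_fit_lmm_requires_positive_scores(default_study, default_truth_scores):
    scores = default_truth_scores.scores.copy()
    scores.iloc[0, 0] = -1.0
    with pytest.raises(ValueError, match="log"):
        pm.fit_lmm(pm.LmmSpec(), default_study.cohort, scores,
                   scores.columns[0])
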