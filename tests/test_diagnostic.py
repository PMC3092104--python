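"""Diagnostic model: pooling, logistic closed forms, stepwise-AIC vs
exhaustive search, AUC/OR/RR oracles, CV harness determinism."""

import itertools

import numpy as np
import pandas as pd
import pytest

import psymetab as pm
from psymetab.diagnostic import MarkerPanel, or_rr, roc_auc, stepwise_aic


class TestPooling:
    def test_default_counts(self, default_study):
        y = pm.pool_psychoses(default_study.cohort)
        assert len(y) == 139
        assert int(y.sum()) == 45
        assert int((y == 0).sum()) == 94

    def test_controls_only_rejected(self, default_study):
        coh = default_study.cohort
        with pytest.raises(ValueError):
            pm.pool_psychoses(coh[coh.role == "control"])

    def test_order_invariance(self, default_study):
        coh = default_study.cohort
        shuffled = coh.sample(frac=1.0, random_state=7)
        a = pm.pool_psychoses(coh).sort_index()
        b = pm.pool_psychoses(shuffled).sort_index()
        pd.testing.assert_series_equal(a, b)


class TestLogistic:
    def test_intercept_only_closed_form(self):
        y = np.r_[np.ones(45), np.zeros(94)]
        fit = pm.fit_logistic(np.empty((139, 0)), y)
        ll = 45 * np.log(45 / 139) + 94 * np.log(94 / 139)
        assert fit.log_likelihood == pytest.approx(ll, rel=1e-10)
        assert fit.aic == pytest.approx(-2 * ll + 2, rel=1e-10)

    def test_uninformative_predictor(self, rng):
        y = np.tile([0, 1], 50)
        x = rng.normal(size=(100, 1))
        fit = pm.fit_logistic(x, y)
        assert abs(fit.params[1]) < 0.5
        assert not fit.separation

    def test_separable_data_flagged(self):
        x = np.r_[np.linspace(-3, -1, 10), np.linspace(1, 3, 10)].reshape(-1, 1)
        y = np.r_[np.zeros(10), np.ones(10)]
        fit = pm.fit_logistic(x, y)
        assert fit.separation

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            pm.fit_logistic(np.ones((5, 1)), np.ones(5))

    def test_constant_predictor_rejected(self):
        with pytest.raises(ValueError):
            pm.fit_logistic(np.ones((6, 1)), np.r_[np.ones(3), np.zeros(3)])


class TestStepwise:
    def _aic_of(self, X, y, subset):
        return pm.fit_logistic(X[list(subset)].to_numpy() if subset
                               else np.empty((len(y), 0)), y).aic

    def test_matches_exhaustive_search(self):
        """Stepwise AIC finds the global 16-subset optimum on nearly all
        simulated panels."""
        agree = 0
        n_sims = 60
        for seed in range(n_sims):
            rng = np.random.default_rng(seed)
            n = 139
            y = np.r_[np.ones(45), np.zeros(94)]
            X = pd.DataFrame(rng.normal(size=(n, 4)), columns=list("abcd"))
            X["a"] += 0.8 * y
            X["b"] += 0.3 * y
            subset, fit = stepwise_aic(X, y)
            best = min((self._aic_of(X, y, s)
                        for k in range(5)
                        for s in itertools.combinations("abcd", k)))
            agree += fit.aic == pytest.approx(best, abs=1e-9)
        assert agree / n_sims >= 0.95

    def test_pure_noise_mostly_selects_empty(self):
        empties = 0
        counts = {}
        for seed in range(60):
            rng = np.random.default_rng(1000 + seed)
            y = np.r_[np.ones(45), np.zeros(94)]
            X = pd.DataFrame(rng.normal(size=(139, 4)), columns=list("abcd"))
            subset, _ = stepwise_aic(X, y)
            key = tuple(subset)
            counts[key] = counts.get(key, 0) + 1
        assert max(counts, key=counts.get) == ()

    def test_dominant_marker_always_selected(self, rng):
        for seed in range(10):
            r = np.random.default_rng(seed)
            y = np.r_[np.ones(40), np.zeros(60)]
            X = pd.DataFrame(r.normal(size=(100, 3)), columns=list("abc"))
            X["b"] += 2.0 * y
            subset, _ = stepwise_aic(X, y)
            assert "b" in subset

    def test_stepwise_beats_trivial_models(self, rng):
        y = np.r_[np.ones(45), np.zeros(94)]
        X = pd.DataFrame(rng.normal(size=(139, 4)), columns=list("abcd"))
        X["a"] += 1.0 * y
        subset, fit = stepwise_aic(X, y)
        assert fit.aic <= self._aic_of(X, y, ()) + 1e-9
        assert fit.aic <= self._aic_of(X, y, tuple("abcd")) + 1e-9


def _brute_auc(scores, labels):
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestAuc:
    def test_perfect_ranking(self):
        assert roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_toy_with_discordant_pair(self):
        scores = [0.9, 0.3, 0.6, 0.1]
        labels = [1, 1, 0, 0]
        assert roc_auc(scores, labels) == pytest.approx(
            _brute_auc(scores, labels))

    def test_brute_force_oracle_random(self, rng):
        for _ in range(10):
            scores = rng.normal(size=30)
            labels = rng.integers(0, 2, 30)
            if labels.min() == labels.max():
                continue
            assert roc_auc(scores, labels) == pytest.approx(
                _brute_auc(scores, labels), abs=1e-12)

    def test_monotone_transform_invariance(self, rng):
        scores = rng.normal(size=40)
        labels = rng.integers(0, 2, 40)
        labels[0], labels[1] = 0, 1
        a = roc_auc(scores, labels)
        assert roc_auc(np.exp(scores), labels) == pytest.approx(a)
        assert roc_auc(3 * scores - 7, labels) == pytest.approx(a)

    def test_null_ranking_near_half(self, rng):
        aucs = [roc_auc(rng.normal(size=200), np.r_[np.ones(100), np.zeros(100)])
                for _ in range(30)]
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.03)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.9], [1, 1])


class TestOrRr:
    def test_perfect_classification_corrected(self):
        probs = np.r_[np.full(10, 0.9), np.full(10, 0.1)]
        labels = np.r_[np.ones(10), np.zeros(10)]
        odds, rr = or_rr(probs, labels)
        assert odds == pytest.approx((10.5 * 10.5) / (0.5 * 0.5))

    def test_null_predictions_near_one(self, rng):
        vals = []
        for _ in range(50):
            probs = rng.random(200)
            labels = rng.integers(0, 2, 200)
            odds, rr = or_rr(probs, labels)
            vals.append((odds, rr))
        odds, rr = np.array(vals).mean(axis=0)
        assert odds == pytest.approx(1.0, abs=0.25)
        assert rr == pytest.approx(1.0, abs=0.15)

    def test_degenerate_all_positive_finite(self):
        probs = np.full(20, 0.9)
        labels = np.r_[np.ones(12), np.zeros(8)]
        odds, rr = or_rr(probs, labels)
        assert np.isfinite(odds) and np.isfinite(rr)
        assert odds > 0 and rr > 0


@pytest.fixture(scope="module")
def panel_and_labels():
    study = pm.generate_study(pm.CohortConfig(seed=2))
    labels = pm.pool_psychoses(study.cohort)
    return pm.marker_panel_from_study(study), labels


class TestRunCv:
    def test_split_sizes(self, panel_and_labels):
        panel, labels = panel_and_labels
        rep = pm.run_cv(panel, labels, n_runs=5, seed=0)
        assert rep.train_size == 93
        assert rep.test_size == 46

    def test_single_run_report(self, panel_and_labels):
        panel, labels = panel_and_labels
        rep = pm.run_cv(panel, labels, n_runs=1, seed=0)
        assert len(rep.runs) == 1
        assert rep.selection_frequency.iloc[0] == 1.0

    def test_frequencies_sum_to_one(self, panel_and_labels):
        panel, labels = panel_and_labels
        rep = pm.run_cv(panel, labels, n_runs=40, seed=3)
        assert rep.selection_frequency.sum() == pytest.approx(1.0, abs=1e-12)

    def test_seed_determinism(self, panel_and_labels):
        panel, labels = panel_and_labels
        a = pm.run_cv(panel, labels, n_runs=25, seed=11)
        b = pm.run_cv(panel, labels, n_runs=25, seed=11)
        pd.testing.assert_frame_equal(a.runs, b.runs)
        pd.testing.assert_series_equal(a.selection_frequency,
                                       b.selection_frequency)

    def test_nonpositive_marker_rejected_for_log(self, panel_and_labels):
        panel, labels = panel_and_labels
        bad = panel.values.copy()
        bad.iloc[0, 0] = -1.0
        with pytest.raises(ValueError):
            pm.run_cv(MarkerPanel(bad), labels, n_runs=2, seed=0)


def test_marker_panel_assembly(default_study):
    panel = pm.marker_panel_from_study(default_study)
    assert list(panel.values.columns) == list(pm.diagnostic.DEFAULT_MARKERS)
    assert len(panel.values) == 278
    assert panel.values.notna().all().all()
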