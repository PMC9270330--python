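"""CIRCLE classifier, Monte Carlo CV machinery, metrics, DeLong comparison."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_curve

from circleicb.classifier import (
    CircleClassifier,
    average_roc_curves,
    build_circle_design,
    build_tmb_design,
    classification_metrics,
    consensus_classify,
    delong_compare,
    monte_carlo_cv,
    optimal_cutoff,
)


class TestCircleClassifier:
    def test_scores_are_probabilities(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(size=(80, 3)), columns=list("abc"))
        y = rng.integers(0, 2, 80)
        model = CircleClassifier().fit(X, y)
        scores = model.score_patients(X)
        assert np.all((scores >= 0) & (scores <= 1))
        assert list(model.feature_names_in_) == list("abc")

    def test_null_features_reduce_to_covariate_model(self):
        rng = np.random.default_rng(1)
        n = 150
        covs = pd.DataFrame({"age": rng.normal(60, 10, n)})
        y = rng.integers(0, 2, n)
        with_null = CircleClassifier().fit(
            pd.concat([pd.DataFrame({"g": np.zeros(n)}), covs], axis=1), y)
        base = CircleClassifier().fit(covs, y)
        np.testing.assert_allclose(
            with_null.coef_[0][1], base.coef_[0][0], atol=1e-5)

    def test_generative_coefficient_recovery(self):
        """Logistic fit recovers known coefficients (n=1,000, fixed seed)."""
        rng = np.random.default_rng(99)
        n = 1000
        X = pd.DataFrame({"g": rng.integers(0, 2, n),
                          "z": rng.normal(size=n)})
        beta = np.array([-1.2, 0.8])
        y = rng.random(n) < 1 / (1 + np.exp(-(0.2 + X.to_numpy() @ beta)))
        model = CircleClassifier().fit(X, y.astype(int))
        # 3-SE window via the logistic information matrix
        p = model.predict_proba(X)[:, 1]
        W = p * (1 - p)
        design = np.c_[np.ones(n), X.to_numpy()]
        cov = np.linalg.inv(design.T @ (design * W[:, None]))
        se = np.sqrt(np.diag(cov))[1:]
        assert np.all(np.abs(model.coef_[0] - beta) < 3 * se)

    def test_json_round_trip(self, tmp_path):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.normal(size=(50, 2)), columns=["a", "b"])
        model = CircleClassifier().fit(X, rng.integers(0, 2, 50))
        model.to_json(tmp_path / "m.json")
        import json
        loaded = json.loads((tmp_path / "m.json").read_text())
        assert loaded["feature_names"] == ["a", "b"]
        np.testing.assert_allclose(loaded["coefficients"], model.coef_[0])


class TestAverageRoc:
    def test_identical_curves_average_to_themselves(self):
        fpr = np.array([0.0, 0.5, 1.0])
        tpr = np.array([0.0, 0.7, 1.0])
        avg = average_roc_curves([(fpr, tpr), (fpr, tpr)])
        assert np.interp(0.5, avg["fpr"], avg["tpr"]) == pytest.approx(0.7)

    def test_diagonal_plus_perfect(self):
        diag = (np.array([0.0, 1.0]), np.array([0.0, 1.0]))
        perfect = (np.array([0.0, 1e-12, 1.0]), np.array([0.0, 1.0, 1.0]))
        avg = average_roc_curves([diag, perfect])
        at_half = avg.loc[np.isclose(avg["fpr"], 0.5), "tpr"].iloc[0]
        assert at_half == pytest.approx(0.75, abs=1e-9)

    def test_average_monotone_nondecreasing(self):
        rng = np.random.default_rng(3)
        curves = []
        for _ in range(5):
            scores = rng.normal(size=60)
            truth = rng.integers(0, 2, 60)
            fpr, tpr, _ = roc_curve(truth, scores)
            curves.append((fpr, tpr))
        avg = average_roc_curves(curves)
        assert np.all(np.diff(avg["tpr"]) >= -1e-12)


class TestOptimalCutoff:
    def test_perfect_classifier_point(self):
        roc = (np.array([0.0, 0.0, 1.0]), np.array([0.0, 1.0, 1.0]),
               np.array([0.9, 0.5, 0.1]))
        assert optimal_cutoff(roc) == pytest.approx(0.5)

    def test_diagonal_minimized_at_half(self):
        fpr = np.linspace(0, 1, 101)
        roc = (fpr, fpr, 1 - fpr)
        # distance sqrt(x^2 + (1-x)^2) is minimized at x = 0.5
        assert optimal_cutoff(roc) == pytest.approx(0.5)

    def test_single_point(self):
        assert optimal_cutoff(([0.2], [0.8], [0.4])) == pytest.approx(0.4)

    def test_tie_takes_lowest_threshold(self):
        roc = (np.array([0.0, 0.2]), np.array([0.8, 1.0]), np.array([0.7, 0.3]))
        # both points at distance 0.2 from (0,1)
        assert optimal_cutoff(roc) == pytest.approx(0.3)


class TestConsensus:
    def test_unanimous(self):
        assert consensus_classify({"p": [True, True, True]}) == {"p": True}

    def test_majority(self):
        assert consensus_classify({"p": [True, True, True, False, False]}) == {"p": True}

    def test_tie_is_non_responder(self):
        assert consensus_classify({"p": [True, True, False, False]}) == {"p": False}

    def test_unvoted_patient_rejected(self):
        with pytest.raises(ValueError):
            consensus_classify({"p": []})


class TestClassificationMetrics:
    def test_confusion_arithmetic(self):
        truth = np.array([1] * 4 + [0] * 6, dtype=bool)
        labels = np.array([1, 1, 1, 0, 1, 0, 0, 0, 0, 0], dtype=bool)
        scores = np.linspace(0.9, 0.1, 10)
        m, _, _ = classification_metrics(truth, labels, scores)
        assert m.sensitivity == pytest.approx(0.75)
        assert m.specificity == pytest.approx(5 / 6)
        assert m.f1 == pytest.approx(0.75)
        assert m.fpr == pytest.approx(1 - m.specificity)
        assert m.fnr == pytest.approx(1 - m.sensitivity)

    def test_identical_score_distributions_theta_zero(self):
        truth = np.array([1, 1, 0, 0, 1, 0], dtype=bool)
        scores = np.array([0.3, 0.6, 0.3, 0.6, 0.9, 0.9])
        _, _, theta = classification_metrics(truth, truth, scores)
        assert theta == pytest.approx(0.0, abs=1e-9)

    def test_perfect_scores_auprc_one(self):
        truth = np.array([1, 1, 1, 0, 0, 0], dtype=bool)
        scores = np.array([0.9, 0.8, 0.7, 0.3, 0.2, 0.1])
        _, auprc, theta = classification_metrics(truth, truth, scores)
        assert auprc == pytest.approx(1.0)
        assert theta > 0

    def test_single_class_truth_rejected(self):
        with pytest.raises(ValueError):
            classification_metrics([1, 1], [1, 0], [0.5, 0.5])


class TestDeLong:
    def test_identical_scores_p_one(self):
        rng = np.random.default_rng(4)
        scores = rng.normal(size=40)
        truth = rng.integers(0, 2, 40).astype(bool)
        auc_a, auc_b, p = delong_compare(scores, scores, truth)
        assert auc_a == pytest.approx(auc_b)
        assert p == 1.0

    def test_perfect_separation_auc_one(self):
        truth = np.array([1, 1, 1, 0, 0, 0], dtype=bool)
        scores = np.array([0.9, 0.8, 0.7, 0.3, 0.2, 0.1])
        auc_a, _, _ = delong_compare(scores, np.random.default_rng(0).normal(size=6),
                                     truth)
        assert auc_a == pytest.approx(1.0)

    def test_auc_matches_exhaustive_concordance(self):
        truth = np.array([1, 0, 1, 0, 1, 0], dtype=bool)
        scores = np.array([0.9, 0.8, 0.6, 0.55, 0.3, 0.1])
        pos, neg = scores[truth], scores[~truth]
        brute = np.mean([
            1.0 if a > b else 0.5 if a == b else 0.0
            for a in pos for b in neg
        ])
        auc, _, _ = delong_compare(scores, scores[::-1], truth)
        assert auc == pytest.approx(brute)

    def test_trapezoid_auc_equals_mann_whitney(self):
        """ROC integration and rank-based concordance agree on random data."""
        rng = np.random.default_rng(7)
        truth = rng.integers(0, 2, 100).astype(bool)
        scores = rng.normal(size=100) + truth * 0.8
        fpr, tpr, _ = roc_curve(truth, scores)
        trap = np.trapezoid(tpr, fpr)
        auc, _, _ = delong_compare(scores, scores * 0 + 0.5 * truth, truth)
        assert trap == pytest.approx(auc, abs=1e-12)

    def test_significant_difference_detected(self):
        rng = np.random.default_rng(8)
        truth = np.repeat([True, False], 100)
        good = truth + rng.normal(0, 0.3, 200)
        noise = rng.normal(size=200)
        _, _, p = delong_compare(good, noise, truth)
        assert p < 0.01


class TestMonteCarloCv:
    def _toy(self, n=160, signal=3.0, seed=0):
        rng = np.random.default_rng(seed)
        y = rng.integers(0, 2, n).astype(bool)
        X = pd.DataFrame({"f": y * signal + rng.normal(size=n)})
        strata = rng.choice(["melanoma", "NSCLC"], n, p=[0.7, 0.3])
        return X, y, strata

    def test_separable_signal_high_auc(self):
        X, y, strata = self._toy(signal=8.0)
        rep = monte_carlo_cv(X, y, strata, n_iter=60, seed=1)
        assert rep.mean_auc >= 0.99

    def test_permuted_labels_null_auc(self):
        X, y, strata = self._toy(signal=3.0, n=400)
        y_perm = np.random.default_rng(11).permutation(y)
        rep = monte_carlo_cv(X, y_perm, strata, n_iter=40, seed=2)
        assert rep.mean_auc == pytest.approx(0.5, abs=0.05)

    def test_same_seed_bit_identical(self):
        X, y, strata = self._toy()
        a = monte_carlo_cv(X, y, strata, n_iter=40, seed=7)
        b = monte_carlo_cv(X, y, strata, n_iter=40, seed=7)
        np.testing.assert_array_equal(a.aucs, b.aucs)
        pd.testing.assert_series_equal(a.consensus_scores, b.consensus_scores)
        pd.testing.assert_series_equal(a.consensus_labels, b.consensus_labels)
        assert a.optimal_cutoff == b.optimal_cutoff

    def test_split_preserves_stratum_proportions(self):
        X, y, strata = self._toy(n=200)
        rep = monte_carlo_cv(X, y, strata, n_iter=40, seed=3)
        for it in rep.per_iteration:
            test_idx = it["test_index"]
            assert len(test_idx) == pytest.approx(0.25 * len(y), abs=2)
            frac_mel = (strata[test_idx] == "melanoma").mean()
            assert frac_mel == pytest.approx((strata == "melanoma").mean(), abs=0.08)

    def test_tiny_stratum_rejected(self):
        X, y, strata = self._toy(n=40)
        strata = strata.astype(object)
        strata[0] = "rare_type"
        with pytest.raises(ValueError, match="rare_type"):
            monte_carlo_cv(X, y, strata, n_iter=2, seed=0)


class TestTmbBaseline:
    def test_panel_equals_exome_when_panel_is_all_genes(self, sim_small):
        coh = sim_small.cohort
        all_genes = {g.gene_id for g in sim_small.genes}
        X = build_tmb_design(coh, all_genes)
        exome_log2 = np.log2(coh.tmb.to_numpy() + 1)
        np.testing.assert_allclose(X["log2_panel_tmb"], exome_log2)

    def test_score_monotone_in_tmb(self, sim_small):
        coh = sim_small.cohort
        all_genes = {g.gene_id for g in sim_small.genes}
        X = build_tmb_design(coh, all_genes)
        included = coh.patients["response"].notna().to_numpy()
        y = coh.patients.loc[included, "response"].astype(bool).to_numpy()
        model = CircleClassifier().fit(X[included], y)
        scores = model.score_patients(X[included])
        order = np.argsort(X.loc[included, "log2_panel_tmb"].to_numpy())
        diffs = np.diff(scores[order])
        assert np.all(diffs >= -1e-12) or np.all(diffs <= 1e-12)

    def test_empty_panel_rejected(self, sim_small):
        with pytest.raises(ValueError):
            build_tmb_design(sim_small.cohort, {"NOT_A_GENE"})


class TestCircleDesign:
    def test_design_columns(self, sim_small):
        from circleicb.cohort import build_feature_matrix
        coh = sim_small.cohort
        fm = build_feature_matrix(coh, sim_small.driver_genes)
        clin = coh.patients.copy()
        clin["log2_tmb"] = np.log2(coh.tmb.to_numpy() + 1)
        X = build_circle_design(fm, clin, sim_small.driver_genes[:2])
        assert "age" in X.columns and "log2_tmb" in X.columns
        assert not any(c.startswith("study_id") for c in X.columns)
        assert sum(c.startswith("tumor_type") for c in X.columns) >= 1
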