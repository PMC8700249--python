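import numpy as np
import pandas as pd
import pytest

from metgrade.evaluation import (
    CvConfig,
    _fold_metrics,
    evaluate,
    hanley_mcneil_se,
    lda_fit,
    low_grade_score,
    stratified_kfold,
)


def _gaussian_table(rng, n_low=20, n_high=40, separation=3.0, m_noise=2):
    """Feature table with one class-shifted column plus noise columns."""
    y = np.repeat([0, 1], [n_low, n_high])
    data = {"signal": y * separation + rng.standard_normal(n_low + n_high)}
    for i in range(m_noise):
        data[f"noise_{i}"] = rng.standard_normal(n_low + n_high)
    table = pd.DataFrame(data)
    table["grade"] = y
    perm = rng.permutation(len(table))
    return table.iloc[perm].reset_index(drop=True)


class TestLdaFit:
    def test_separable_clusters_fit_perfectly(self, rng):
        X = np.vstack([rng.standard_normal((20, 2)), rng.standard_normal((20, 2)) + 8])
        y = np.repeat([0, 1], 20)
        clf = lda_fit(X, y)
        assert (clf.predict(X) == y).all()

    def test_score_affine_invariant(self, rng):
        X = rng.standard_normal((40, 3))
        y = (rng.random(40) < 0.5).astype(int)
        y[:2] = [0, 1]
        s1 = low_grade_score(lda_fit(X, y), X)
        X2 = X * np.array([10.0, 0.2, 3.0]) + np.array([5.0, -2.0, 0.0])
        s2 = low_grade_score(lda_fit(X2, y), X2)
        np.testing.assert_allclose(s1, s2, atol=1e-8)

    def test_identical_class_distributions_hit_bayes_rate(self, rng):
        # with no class signal, accuracy converges to the majority prior
        accs = []
        for rep in range(10):
            X = rng.standard_normal((150, 2))
            y = np.repeat([0, 1], [45, 105])
            clf = lda_fit(X, y)
            accs.append((clf.predict(X) == y).mean())
        assert np.mean(accs) == pytest.approx(0.7, abs=0.08)

    def test_requires_two_populated_classes(self, rng):
        X = rng.standard_normal((10, 2))
        with pytest.raises(ValueError):
            lda_fit(X, np.zeros(10, dtype=int))


class TestStratifiedKfold:
    def test_imbalanced_folds_keep_class_ratio(self):
        y = np.repeat([1, 0], [39, 17])
        folds = stratified_kfold(y, CvConfig(k=5, seed=3))
        for _, te in folds:
            n_high = int((y[te] == 1).sum())
            n_low = int((y[te] == 0).sum())
            assert n_high in (7, 8)
            assert n_low in (3, 4)

    def test_folds_disjoint_and_covering(self):
        y = np.repeat([1, 0], [14, 6])
        folds = stratified_kfold(y, CvConfig(k=4, seed=0))
        seen = np.concatenate([te for _, te in folds])
        assert sorted(seen) == list(range(20))

    def test_leave_one_out_limit(self):
        y = np.repeat([1, 0], [3, 3])
        folds = stratified_kfold(y, CvConfig(k=3, seed=0))
        assert len(folds) == 3

    def test_seed_determinism(self):
        y = np.repeat([1, 0], [20, 10])
        f1 = stratified_kfold(y, CvConfig(k=5, seed=7))
        f2 = stratified_kfold(y, CvConfig(k=5, seed=7))
        for (a, _), (b, _) in zip(f1, f2):
            np.testing.assert_array_equal(a, b)

    def test_k_above_minority_count_rejected(self):
        y = np.repeat([1, 0], [20, 3])
        with pytest.raises(ValueError, match="smaller k"):
            stratified_kfold(y, CvConfig(k=5, seed=0))


class TestMetrics:
    def test_toy_confusion_counts(self):
        # truth: 4 low (3 predicted low), 6 high (5 predicted high)
        y_true = np.array([0, 0, 0, 0, 1, 1, 1, 1, 1, 1])
        y_pred = np.array([0, 0, 0, 1, 1, 1, 1, 1, 1, 0])
        m = _fold_metrics(y_true, y_pred)
        assert m.sensitivity == pytest.approx(0.75)
        assert m.specificity == pytest.approx(5 / 6)
        assert m.accuracy == pytest.approx(0.8)

    def test_hanley_mcneil_matches_direct_formula(self):
        auc, n1, n2 = 0.7891, 17, 39
        q1 = auc / (2 - auc)
        q2 = 2 * auc**2 / (1 + auc)
        var = (auc * (1 - auc) + (n1 - 1) * (q1 - auc**2) + (n2 - 1) * (q2 - auc**2)) / (n1 * n2)
        assert hanley_mcneil_se(auc, n1, n2) == pytest.approx(np.sqrt(var))


class TestEvaluate:
    def test_separable_table_perfect_metrics(self, rng):
        table = _gaussian_table(rng, separation=50.0)
        report = evaluate(table, ["signal"], CvConfig(k=5, seed=0))
        assert report.accuracy == pytest.approx(1.0)
        assert report.auc == pytest.approx(1.0)

    def test_shuffled_labels_give_chance_auc(self, rng):
        aucs = []
        for rep in range(20):
            table = _gaussian_table(rng, separation=2.0)
            shuffled = table.copy()
            shuffled["grade"] = rng.permutation(shuffled["grade"].to_numpy())
            if shuffled["grade"].min() == shuffled["grade"].max():
                continue
            report = evaluate(shuffled, ["signal", "noise_0"], CvConfig(k=5, seed=rep))
            aucs.append(report.auc)
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.15)

    def test_auc_equals_normalized_mann_whitney(self, rng):
        from scipy.stats import mannwhitneyu

        table = _gaussian_table(rng, separation=1.5)
        report = evaluate(table, ["signal"], CvConfig(k=4, seed=1))
        scores = report.pooled_scores
        y = report.pooled_labels
        u = mannwhitneyu(scores[y == 0], scores[y == 1], alternative="two-sided").statistic
        expected = u / ((y == 0).sum() * (y == 1).sum())
        assert report.auc == pytest.approx(expected, abs=1e-10)

    def test_accuracy_decomposes_into_class_weighted_rates(self, rng):
        table = _gaussian_table(rng, separation=1.0)
        report = evaluate(table, ["signal"], CvConfig(k=5, seed=2))
        n = report.n_low + report.n_high
        recomposed = (
            report.pooled_sensitivity * report.n_low
            + report.pooled_specificity * report.n_high
        ) / n
        assert report.pooled_accuracy == pytest.approx(recomposed, abs=1e-12)

    def test_nested_selection_mode(self, rng):
        table = _gaussian_table(rng, separation=4.0, m_noise=4)
        report = evaluate(table, None, CvConfig(k=4, seed=0), nested_selection=True)
        assert report.selection_mode.startswith("nested")
        assert report.accuracy > 0.8

    def test_imbalance_does_not_zero_out_sensitivity(self, rng):
        """Moderate separation at 70/30 imbalance must keep sensitivity > 0.2."""
        table = _gaussian_table(rng, n_low=17, n_high=39, separation=2.0)
        report = evaluate(table, ["signal"], CvConfig(k=5, seed=0))
        assert report.sensitivity > 0.2
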