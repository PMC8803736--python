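import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from depstack import (
    ExperimentConfig,
    ScenarioConfig,
    compute_metrics,
    f1_from_pr,
    friedman_test,
    generate_feature_table,
    improvement_pp,
    run_experiment,
    stratified_split,
    wilcoxon_pairwise,
)
from depstack.imbalance import SmoteConfig, smote
from depstack.stacking import BASE_KINDS, LearnerSpec, make_estimator


class TestStratifiedSplit:
    def test_study_class_sizes(self):
        y = np.array([1] * 130 + [0] * 320)
        X = np.zeros((450, 1))
        tr, te = stratified_split(X, y, test_fraction=0.25, seed=0)
        assert (y[te] == 1).sum() in (32, 33)
        assert abs((y[te] == 0).sum() - 80) <= 1

    def test_partition(self, rng):
        y = rng.integers(0, 2, 40)
        y[:4] = [0, 0, 1, 1]
        X = np.zeros((40, 1))
        tr, te = stratified_split(X, y, seed=3)
        assert sorted(np.concatenate([tr, te])) == list(range(40))
        assert not set(tr) & set(te)

    def test_seed_reproducible(self, rng):
        y = np.array([0] * 20 + [1] * 20)
        X = np.zeros((40, 1))
        a = stratified_split(X, y, seed=5)
        b = stratified_split(X, y, seed=5)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])

    def test_tiny_class_rejected(self):
        y = np.array([0, 0, 0, 1])
        with pytest.raises(ValueError, match="at least 2"):
            stratified_split(np.zeros((4, 1)), y)


class TestMetrics:
    def test_perfect_prediction(self):
        m = compute_metrics([1, 0, 1], [1, 0, 1])
        assert (m.accuracy, m.precision, m.recall, m.f1) == (1, 1, 1, 1)

    def test_hand_confusion_matrix(self):
        m = compute_metrics([1, 1, 0, 0], [1, 0, 0, 0])
        assert (m.tp, m.fp, m.tn, m.fn) == (1, 0, 2, 1)
        assert m.precision == 1.0
        assert m.recall == 0.5
        assert m.f1 == pytest.approx(2 / 3)
        assert m.accuracy == 0.75

    def test_no_positive_predictions_precision_zero(self, caplog):
        with caplog.at_level("WARNING"):
            m = compute_metrics([1, 1, 0], [0, 0, 0])
            assert m.precision == 0.0
        assert any("precision" in r.message for r in caplog.records)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            compute_metrics([], [])

    def test_positive_class_flip(self):
        m = compute_metrics([1, 1, 0, 0], [1, 0, 0, 0], positive_class=0)
        assert m.recall == 1.0  # both true 0s predicted 0
        assert m.precision == pytest.approx(2 / 3)


class TestReportArithmetic:
    @pytest.mark.parametrize(
        "p,r,expected",
        [(0.8791, 1.0000, 0.9357), (0.8242, 0.9375, 0.8772)],
    )
    def test_f1_report_rounding(self, p, r, expected):
        assert f1_from_pr(p, r, digits=4) == expected

    def test_equal_arguments_identity(self):
        assert f1_from_pr(0.7, 0.7) == pytest.approx(0.7)

    def test_zero_zero_rejected(self):
        with pytest.raises(ValueError):
            f1_from_pr(0.0, 0.0)

    @pytest.mark.parametrize(
        "after,before,expected",
        [(0.9313, 0.8496, 8.17), (0.9563, 0.9027, 5.36), (0.62, 0.62, 0.0)],
    )
    def test_improvement_percentage_points(self, after, before, expected):
        assert improvement_pp(after, before) == expected


def _friedman_oracle(arr):
    """Brute-force Friedman statistic from mid-ranks with tie correction."""
    n, k = arr.shape
    ranks = np.vstack([stats.rankdata(row) for row in arr])
    rj = ranks.sum(axis=0)
    ties = 0.0
    for row in arr:
        _, counts = np.unique(row, return_counts=True)
        ties += float(np.sum(counts**3 - counts))
    c = 1 - ties / (n * k * (k**2 - 1))
    return (12.0 / (n * k * (k + 1)) * float(np.sum(rj**2)) - 3 * n * (k + 1)) / c


class TestFriedman:
    def test_identical_columns_statistic_zero(self):
        scores = np.tile(np.arange(4.0)[:, None], (1, 3))
        stat, dof, p = friedman_test(scores)
        assert stat == 0.0 and dof == 2 and p == 1.0

    def test_consistent_ordering_closed_form(self):
        # 3 methods, 4 units, strictly consistent ordering -> statistic 8
        scores = np.array([[1, 2, 3]] * 4, dtype=float) + \
            np.arange(4)[:, None] * 10
        stat, dof, p = friedman_test(scores)
        assert stat == pytest.approx(8.0)
        assert dof == 2

    def test_matches_brute_force_on_random_matrices(self):
        r = np.random.default_rng(0)
        for _ in range(30):
            n = int(r.integers(2, 6))
            k = int(r.integers(2, 5))
            arr = np.round(r.uniform(size=(n, k)), 1)  # ties common
            stat, dof, _ = friedman_test(arr)
            if np.ptp(arr, axis=1).max() == 0:
                assert stat == 0.0
                continue
            assert stat == pytest.approx(_friedman_oracle(arr), abs=1e-8)
            assert dof == k - 1

    def test_column_permutation_invariant(self, rng):
        arr = rng.uniform(size=(5, 4))
        stat, _, _ = friedman_test(arr)
        stat_p, _, _ = friedman_test(arr[:, [2, 0, 3, 1]])
        assert stat == pytest.approx(stat_p)

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            friedman_test(np.ones((4, 1)))


class TestWilcoxon:
    def test_self_comparison_unit_p(self, caplog):
        scores = pd.DataFrame({"a": [1.0, 2, 3, 4, 5, 6], "b": [1.0, 2, 3, 4, 5, 6]})
        with caplog.at_level("WARNING"):
            mat = wilcoxon_pairwise(scores)
        assert mat.loc["a", "b"] == 1.0
        assert (np.diag(mat) == 1).all()

    def test_exact_p_for_uniform_dominance(self):
        # one column uniformly greater over 6 units: two-sided exact p = 2/2^6
        scores = pd.DataFrame(
            {"a": [1.0, 2, 3, 4, 5, 6], "b": [2.0, 3, 4, 5, 6, 7]}
        )
        mat = wilcoxon_pairwise(scores)
        assert mat.loc["a", "b"] == pytest.approx(2 / 64)

    def test_exact_matches_sign_enumeration(self, rng):
        # tie-free differences, n <= 10: enumerate all sign assignments
        d = rng.uniform(0.1, 1.0, 8) * rng.choice([-1, 1], 8)
        scores = pd.DataFrame({"a": np.zeros(8), "b": -d})
        p_pkg = wilcoxon_pairwise(scores).loc["a", "b"]

        ranks = stats.rankdata(np.abs(d))
        w_obs = min(ranks[d > 0].sum(), ranks[d < 0].sum())
        count = 0
        for signs in itertools.product([0, 1], repeat=8):
            w_pos = sum(r for r, s in zip(ranks, signs) if s)
            w = min(w_pos, ranks.sum() - w_pos)
            if w <= w_obs:
                count += 1
        assert p_pkg == pytest.approx(min(1.0, count / 2**8))

    def test_symmetry(self, rng):
        scores = pd.DataFrame(rng.uniform(size=(8, 3)), columns=list("abc"))
        mat = wilcoxon_pairwise(scores)
        np.testing.assert_allclose(mat.to_numpy(), mat.to_numpy().T)


class TestSmoteRecallInvariant:
    def test_balancing_does_not_reduce_minority_recall(self):
        """Training-set SMOTE must not cost minority (depressed) recall for
        the regularized logistic learner, averaged over 20 seeds on the
        default scenario."""
        recalls_u, recalls_b = [], []
        for seed in range(20):
            table = generate_feature_table(ScenarioConfig(), seed=seed)
            tr, te = stratified_split(table.X, table.labels, seed=seed)
            spec = LearnerSpec("lr_l2", {"C": 1.0})
            est = make_estimator(spec, seed=seed)
            est.fit(table.X[tr], table.labels[tr])
            recalls_u.append(
                compute_metrics(table.labels[te], est.predict(table.X[te])).recall
            )
            Xb, yb = smote(table.X[tr], table.labels[tr], SmoteConfig(seed=seed))
            est_b = make_estimator(spec, seed=seed)
            est_b.fit(Xb, yb)
            recalls_b.append(
                compute_metrics(table.labels[te], est_b.predict(table.X[te])).recall
            )
        assert np.mean(recalls_b) >= np.mean(recalls_u)


@pytest.fixture(scope="module")
def small_report():
    table = generate_feature_table(
        ScenarioConfig(n_depressed=24, n_control=40, effect_size=1.5), seed=5
    )
    cfg = ExperimentConfig(
        cv_folds=4,
        grid_cv_folds=3,
        stacking_folds=3,
        smote_k=3,
        seed=5,
        grids={kind: [{}] for kind in BASE_KINDS},
    )
    return run_experiment(table, cfg)


class TestRunExperiment:
    def test_three_models_six_methods_four_metrics(self, small_report):
        tm = small_report.test_metrics
        assert tm.shape == (18, 4)  # 3 models x 6 methods, 4 metric columns
        assert set(tm.index.get_level_values("model")) == {
            "textual", "behavior", "both",
        }
        assert ((tm >= 0) & (tm <= 1)).all().all()

    def test_f1_consistent_with_own_precision_recall(self, small_report):
        for _, row in small_report.test_metrics.iterrows():
            if row["precision"] + row["recall"] > 0:
                assert row["f1"] == pytest.approx(
                    f1_from_pr(row["precision"], row["recall"])
                )
            assert min(row["precision"], row["recall"]) <= row["f1"] + 1e-12
            assert row["f1"] <= max(row["precision"], row["recall"]) + 1e-12

    def test_balance_table_has_six_improvement_cells(self, small_report):
        bal = small_report.balance
        assert len(bal) == 6
        for _, row in bal.iterrows():
            assert row["improve_pp"] == improvement_pp(
                row["accuracy_balanced"], row["accuracy_unbalanced"]
            )

    def test_rank_test_outputs_paired_and_complete(self, small_report):
        for model_name, cv in small_report.cv_scores.items():
            assert cv.shape == (4, 6)
            assert not cv.isna().any().any()
            stat, dof, p = small_report.friedman[model_name]
            assert dof == 5 and 0 <= p <= 1
            wil = small_report.wilcoxon[model_name]
            np.testing.assert_allclose(wil.to_numpy(), wil.to_numpy().T)

    def test_unlabeled_table_rejected(self):
        table = generate_feature_table(
            ScenarioConfig(n_depressed=10, n_control=10), seed=0
        )
        table.labels = None
        with pytest.raises(ValueError, match="labeled"):
            run_experiment(table)
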