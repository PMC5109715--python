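"""Performance metrics, bootstrap CV, Wilcoxon comparison, feature search."""

from itertools import product

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from chromclass import (
    ClassifierSpec,
    ConfusionCounts,
    bootstrap_cv,
    compute_auc,
    compute_metrics,
    forward_best_first,
    property_importance,
    wilcoxon_compare,
)


class TestMetrics:
    def test_perfect_classifier(self):
        m = compute_metrics(ConfusionCounts(tp=5, fp=0, tn=5, fn=0))
        assert m == {"precision": 1.0, "recall": 1.0, "f_score": 1.0, "mcc": 1.0}

    def test_mcc_against_direct_formula(self):
        m = compute_metrics(ConfusionCounts(tp=3, fp=1, tn=4, fn=2))
        assert m["mcc"] == pytest.approx(10 / np.sqrt(600))

    def test_no_positive_predictions_yields_zero_precision(self, caplog):
        with caplog.at_level("WARNING"):
            m = compute_metrics(ConfusionCounts(tp=0, fp=0, tn=5, fn=5))
        assert m["precision"] == 0.0
        assert "degenerate" in caplog.text

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics(ConfusionCounts(0, 0, 0, 0))

    def test_mcc_symmetric_under_joint_swap(self, rng):
        """Swapping labels and predictions together leaves MCC unchanged."""
        for _ in range(20):
            tp, fp, tn, fn = rng.integers(1, 20, 4)
            m1 = compute_metrics(ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn))
            m2 = compute_metrics(ConfusionCounts(tp=tn, fp=fn, tn=tp, fn=fp))
            assert m1["mcc"] == pytest.approx(m2["mcc"])
            assert -1 <= m1["mcc"] <= 1


def auc_pair_oracle(scores, labels):
    """O(n^2) Mann-Whitney pair count: ties contribute one half."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestAUC:
    def test_perfect_separation(self):
        assert compute_auc([0.9, 0.8, 0.4, 0.3], [1, 1, 0, 0]) == 1.0

    def test_all_ties_give_half(self):
        assert compute_auc([0.5] * 6, [1, 1, 1, 0, 0, 0]) == 0.5

    def test_matches_pair_count_oracle(self, rng):
        for _ in range(20):
            scores = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], size=20)
            labels = rng.integers(0, 2, 20)
            if labels.sum() in (0, 20):
                continue
            assert compute_auc(scores, labels) == pytest.approx(
                auc_pair_oracle(scores, labels))

    def test_invariant_under_monotone_transform(self, rng):
        scores = rng.normal(size=30)
        labels = (rng.random(30) < 0.5).astype(int)
        labels[0], labels[1] = 0, 1
        base = compute_auc(scores, labels)
        for f in (np.exp, np.tanh, lambda s: 3 * s + 7):
            assert compute_auc(f(scores), labels) == pytest.approx(base)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            compute_auc([0.1, 0.2], [1, 1])


def wilcoxon_sign_flip_oracle(diffs):
    """Exact two-sided signed-rank p by enumerating all sign assignments."""
    d = np.asarray(diffs, float)
    d = d[d != 0]
    ranks = rankdata(np.abs(d))
    w = ranks[d > 0].sum()
    dist = np.array([
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in product([0, 1], repeat=len(d))
    ])
    return min(1.0, 2 * min((dist <= w).mean(), (dist >= w).mean()))


class TestWilcoxon:
    def test_identical_vectors_give_one(self, caplog):
        with caplog.at_level("WARNING"):
            assert wilcoxon_compare([1, 2, 3, 4, 5], [1, 2, 3, 4, 5]) == 1.0
        assert "zero" in caplog.text

    def test_ten_positive_differences(self):
        a = np.arange(1, 11) * 0.1
        assert wilcoxon_compare(a + 0.05, a - 0.05) == pytest.approx(2 / 2**10)

    def test_matches_exact_enumeration(self, rng):
        for _ in range(15):
            n = int(rng.integers(6, 13))
            d = rng.normal(0.2, 1.0, n)
            while len(set(np.abs(d))) < n or (d == 0).any():
                d = rng.normal(0.2, 1.0, n)
            b = rng.normal(size=n)
            p = wilcoxon_compare(b + d, b)
            assert p == pytest.approx(wilcoxon_sign_flip_oracle(d), abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_compare([1, 2], [1, 2, 3])


def _planted_dataset(n=80, n_noise_blocks=2, seed=0, redundant=False):
    """A balanced dataset where only the PD block carries signal."""
    rng = np.random.default_rng(seed)
    y = np.array([1] * (n // 2) + [0] * (n // 2))
    blocks = {}
    signal = np.where(y[:, None] == 1,
                      rng.random((n, 4)) < 0.9, rng.random((n, 4)) < 0.1)
    blocks["PD"] = signal.astype(int)
    if redundant:
        blocks["Ind_PTM"] = signal.astype(int).copy()
    for i, name in enumerate(["N_DBD", "N_PPI"][:n_noise_blocks]):
        blocks[name] = rng.integers(0, 2, (n, 2))
    cols, data = [], []
    for name, arr in blocks.items():
        for j in range(arr.shape[1]):
            cols.append(f"{name}.b{j}")
        data.append(arr)
    X = pd.DataFrame(np.hstack(data), columns=cols)
    return X, y


FAST_RF = ClassifierSpec(params={"n_estimators": 60})


class TestBootstrapCV:
    def test_record_count_is_runs_times_folds(self):
        X, y = _planted_dataset()
        cv = bootstrap_cv(X, y, FAST_RF, n_runs=10, n_folds=5, seed=0)
        assert len(cv) == 50
        assert set(cv["run"]) == set(range(10)) and set(cv["fold"]) == set(range(5))

    def test_separable_data_scores_high(self):
        X, y = _planted_dataset(seed=1)
        cv = bootstrap_cv(X, y, FAST_RF, property_subset=["PD"],
                          n_runs=3, n_folds=5, seed=1)
        assert cv["auc"].mean() >= 0.95

    def test_permuted_labels_score_at_chance(self, rng):
        X, y = _planted_dataset(seed=2)
        y_perm = rng.permutation(y)
        cv = bootstrap_cv(X, y_perm, FAST_RF, n_runs=4, n_folds=5, seed=2)
        assert 0.4 <= cv["auc"].mean() <= 0.6

    def test_metric_ranges(self):
        X, y = _planted_dataset(seed=3)
        cv = bootstrap_cv(X, y, FAST_RF, n_runs=2, n_folds=5, seed=3)
        for col in ("precision", "recall", "f_score", "auc"):
            assert cv[col].between(0, 1).all()
        assert cv["mcc"].between(-1, 1).all()

    def test_grid_searched_knn_runs(self):
        X, y = _planted_dataset(n=60, seed=4)
        spec = ClassifierSpec("kNN", grid={"n_neighbors": [3, 5]})
        cv = bootstrap_cv(X, y, spec, n_runs=1, n_folds=3, seed=4)
        assert len(cv) == 3 and cv["auc"].mean() > 0.7


class TestPropertyScoring:
    def test_planted_block_ranks_first_on_both_scores(self):
        X, y = _planted_dataset(seed=5)
        table = property_importance(X, y, FAST_RF, n_runs=2, n_folds=3, seed=5)
        assert table.iloc[0]["property"] == "PD"
        assert table.set_index("property")["importance"].idxmax() == "PD"

    def test_importances_normalized(self):
        X, y = _planted_dataset(seed=6)
        table = property_importance(X, y, FAST_RF, n_runs=1, n_folds=3, seed=6)
        assert table["importance"].sum() == pytest.approx(1.0)

    def test_noise_block_scores_near_chance(self):
        X, y = _planted_dataset(seed=7)
        table = property_importance(X, y, FAST_RF, n_runs=4, n_folds=5, seed=7)
        noise_auc = table.set_index("property").loc["N_DBD", "mean_auc"]
        assert 0.4 <= noise_auc <= 0.6

    def test_non_forest_spec_reports_auc_only(self, caplog):
        X, y = _planted_dataset(n=40, seed=8)
        with caplog.at_level("WARNING"):
            table = property_importance(
                X, y, ClassifierSpec("GNB"), n_runs=1, n_folds=3, seed=8)
        assert table["importance"].isna().all()
        assert table["mean_auc"].notna().all()


class TestForwardSearch:
    def test_single_property_trace(self):
        X, y = _planted_dataset(seed=9)
        trace = forward_best_first(X[[c for c in X.columns if c.startswith("PD")]],
                                   y, FAST_RF, n_runs=2, n_folds=3, seed=9)
        assert trace.properties == ["PD"] and trace.best_subset == ["PD"]

    def test_dominant_block_selected_first_and_copy_not_significant(self):
        X, y = _planted_dataset(seed=10, redundant=True)
        trace = forward_best_first(X, y, FAST_RF, n_runs=3, n_folds=4, seed=10)
        assert trace.properties[0] in ("PD", "Ind_PTM")  # the two identical copies
        redundant_step = trace.steps[1]
        assert redundant_step.wilcoxon_p is None or redundant_step.wilcoxon_p > 0.05

    def test_full_trace_recorded_even_when_auc_drops(self):
        X, y = _planted_dataset(seed=11)
        trace = forward_best_first(X, y, FAST_RF, n_runs=2, n_folds=3, seed=11)
        assert len(trace.steps) == len(
            {c.split(".")[0] for c in X.columns})
        assert all(s.mean_auc is not None for s in trace.steps)
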