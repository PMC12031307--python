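"""Benchmark machinery: CV pairing, signed-rank test, letters, metrics."""

import itertools

import numpy as np
import pytest
from scipy import stats

from bisfruit import (
    ConfusionMatrix,
    CVSettings,
    FeatureTable,
    ModelSpec,
    assign_letters,
    confusion_metrics,
    grid_search_cv,
    pca_embed,
    wilcoxon_compare,
)
from bisfruit.ml_bench import (
    confusion_from_predictions,
    confusion_metrics_per_class,
    evaluate_holdout,
    exact_signed_rank_p,
    fold_assignment_hash,
)


def make_blobs_table(n=120, sep=4.0, seed=0, kind="bio-raw"):
    rng = np.random.default_rng(seed)
    half = n // 2
    X = np.vstack(
        [rng.normal(0, 1, (half, 5)), rng.normal(sep, 1, (n - half, 5))]
    )
    y = np.array(["cold"] * half + ["room"] * (n - half))
    order = rng.permutation(n)
    return FeatureTable(
        kind=kind,
        instance_ids=tuple(f"i{i}" for i in range(n)),
        feature_names=tuple(f"f{j}" for j in range(5)),
        X=X[order],
        y=y[order],
    )


def brute_force_signed_rank_p(diffs):
    """Enumerate all 2^n sign assignments of |d| and tally W+ two-sided."""
    d = np.asarray(diffs, float)
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n = len(d)
    ws = []
    for signs in itertools.product([0, 1], repeat=n):
        ws.append(sum(r for s, r in zip(signs, ranks) if s))
    ws = np.asarray(ws)
    p_le = np.mean(ws <= w_obs + 1e-12)
    p_ge = np.mean(ws >= w_obs - 1e-12)
    return min(1.0, 2 * min(p_le, p_ge))


class TestGridSearchCV:
    def test_separable_blobs_reach_perfect_accuracy(self):
        table = make_blobs_table(sep=6.0)
        res = grid_search_cv(
            table, ModelSpec("SVM", grid={"kernel": ["linear"], "C": [1.0]}),
            CVSettings(seed=0),
        )
        assert res.mean == 1.0
        assert len(res.accuracies) == 50

    def test_label_permutation_gives_chance_level(self):
        rng = np.random.default_rng(11)
        table = make_blobs_table(sep=5.0, seed=1)
        permuted = FeatureTable(
            kind=table.kind,
            instance_ids=table.instance_ids,
            feature_names=table.feature_names,
            X=table.X,
            y=rng.permutation(table.y),
        )
        res = grid_search_cv(
            permuted, ModelSpec("SVM", grid={"kernel": ["linear"], "C": [1.0]}),
            CVSettings(seed=0),
        )
        # chance is 0.5; 3 sd of a fold mean over 50 folds of ~12 samples
        assert abs(res.mean - 0.5) < 3 * res.sd

    def test_seeded_end_to_end_determinism(self):
        table = make_blobs_table(sep=1.0, seed=7)
        spec = ModelSpec("SVM")
        a = grid_search_cv(table, spec, CVSettings(seed=3))
        b = grid_search_cv(table, spec, CVSettings(seed=3))
        np.testing.assert_array_equal(a.accuracies, b.accuracies)
        assert a.best_params == b.best_params

    def test_selection_ignores_rows_outside_train_table(self):
        # model selection sees only the training table: its output cannot
        # depend on any other data
        table = make_blobs_table(sep=1.5, seed=5)
        res1 = grid_search_cv(table, ModelSpec("kNN"), CVSettings(seed=1))
        _unrelated = make_blobs_table(sep=0.1, seed=99)
        res2 = grid_search_cv(table, ModelSpec("kNN"), CVSettings(seed=1))
        np.testing.assert_array_equal(res1.accuracies, res2.accuracies)

    def test_fold_hash_shared_across_feature_sets(self):
        ya = make_blobs_table(seed=2).y
        settings = CVSettings(seed=4)
        assert fold_assignment_hash(ya, settings) == fold_assignment_hash(
            ya.copy(), settings
        )

    def test_accuracy_vector_length_is_repeats_times_folds(self):
        table = make_blobs_table()
        res = grid_search_cv(
            table, ModelSpec("NB"), CVSettings(n_repeats=2, n_folds=5, seed=0)
        )
        assert len(res.accuracies) == 10


class TestWilcoxon:
    def test_identical_vectors_give_p_one(self):
        a = np.full(50, 0.8)
        cmp_ = wilcoxon_compare(a, a.copy())
        assert cmp_.p_value == 1.0
        assert cmp_.direction == 0

    def test_all_positive_differences_highly_significant(self):
        rng = np.random.default_rng(0)
        b = rng.uniform(0.6, 0.9, 50)
        a = b + rng.uniform(0.01, 0.05, 50)
        cmp_ = wilcoxon_compare(a, b)
        assert cmp_.p_value < 0.001
        assert cmp_.direction == 1

    @pytest.mark.parametrize("seed", range(6))
    def test_exact_tail_matches_brute_enumeration_n8(self, seed):
        rng = np.random.default_rng(seed)
        d = rng.normal(0.01, 0.03, 8)
        d = d[d != 0]
        assert exact_signed_rank_p(d) == pytest.approx(
            brute_force_signed_rank_p(d), abs=1e-12
        )

    def test_exact_tail_with_ties_matches_enumeration(self):
        d = np.array([0.1, 0.1, -0.1, 0.2, 0.2, 0.3, -0.2, 0.1])
        assert exact_signed_rank_p(d) == pytest.approx(
            brute_force_signed_rank_p(d), abs=1e-12
        )

    def test_unpaired_lengths_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_compare(np.ones(10), np.ones(9))


class TestLetters:
    def test_no_significant_pairs_share_one_letter(self):
        p = np.ones((3, 3))
        assert assign_letters(p) == ["a", "a", "a"]

    def test_all_pairs_significant_get_distinct_letters(self):
        p = np.full((3, 3), 0.001)
        np.fill_diagonal(p, 1.0)
        assert assign_letters(p) == ["a", "b", "c"]

    def test_progressive_pattern_a_b_c(self):
        # raw vs delta, delta vs delta+diam, raw vs delta+diam all significant
        p = np.array([[1.0, 0.01, 0.001], [0.01, 1.0, 0.04], [0.001, 0.04, 1.0]])
        assert assign_letters(p) == ["a", "b", "c"]

    def test_intransitive_pattern_gets_overlap(self):
        # 1~2 ns, 2~3 ns, but 1 vs 3 significant -> middle row bridges
        p = np.array([[1.0, 0.5, 0.01], [0.5, 1.0, 0.5], [0.01, 0.5, 1.0]])
        assert assign_letters(p) == ["a", "ab", "b"]


class TestConfusionMetrics:
    def test_perfect_classifier(self):
        cm = ConfusionMatrix(tp=10, fp=0, fn=0, tn=12)
        m = confusion_metrics(cm)
        assert all(v == 1.0 for v in m.values())

    def test_closed_form_example(self):
        m = confusion_metrics(ConfusionMatrix(tp=8, fp=2, fn=2, tn=8))
        assert m == pytest.approx(
            {"accuracy": 0.8, "precision": 0.8, "recall": 0.8, "f1": 0.8}
        )

    def test_f1_is_harmonic_mean_on_random_matrices(self):
        rng = np.random.default_rng(1)
        checked = 0
        for _ in range(200):
            cm = ConfusionMatrix(*(int(v) for v in rng.integers(0, 40, 4)))
            if cm.total == 0:
                continue
            m = confusion_metrics(cm)
            if np.isnan(m["f1"]):
                continue
            harmonic = 2 / (1 / m["precision"] + 1 / m["recall"])
            assert m["f1"] == pytest.approx(harmonic, rel=1e-12)
            checked += 1
        assert checked > 150

    def test_undefined_precision_flagged_as_nan(self):
        m = confusion_metrics(ConfusionMatrix(tp=0, fp=0, fn=3, tn=7))
        assert np.isnan(m["precision"])

    def test_per_class_swaps_positive(self):
        cm = ConfusionMatrix(tp=5, fp=1, fn=2, tn=9)
        per = confusion_metrics_per_class(cm)
        assert per["cold"]["recall"] == pytest.approx(9 / 10)
        assert per["room"]["recall"] == pytest.approx(5 / 7)


class TestHoldout:
    def test_metrics_consistent_with_matrix(self):
        train = make_blobs_table(n=100, sep=2.0, seed=3)
        test = make_blobs_table(n=40, sep=2.0, seed=4)
        res = evaluate_holdout(train, test, "LDA", {}, seed=0)
        cm = res.test_matrix
        assert cm.total == 40
        recomputed = confusion_metrics(cm)
        assert recomputed == res.test_metrics

    def test_feature_mismatch_rejected(self):
        train = make_blobs_table(n=60, seed=5)
        test = FeatureTable(
            kind=train.kind,
            instance_ids=train.instance_ids[:10],
            feature_names=tuple(f"g{j}" for j in range(5)),
            X=train.X[:10],
            y=train.y[:10],
        )
        with pytest.raises(ValueError):
            evaluate_holdout(train, test, "LDA", {})


class TestPCA:
    def test_explained_variance_nonincreasing(self):
        table = make_blobs_table(n=80, seed=6)
        _, ratios = pca_embed(table, 4)
        assert np.all(np.diff(ratios) <= 1e-12)
        assert ratios.sum() <= 1.0 + 1e-9

    def test_rank_deficient_data_has_zero_third_component(self):
        rng = np.random.default_rng(7)
        basis = rng.normal(size=(2, 5))
        coeffs = rng.normal(size=(60, 2))
        X = coeffs @ basis
        table = FeatureTable(
            kind="bio-raw",
            instance_ids=tuple(f"i{i}" for i in range(60)),
            feature_names=tuple(f"f{j}" for j in range(5)),
            X=X,
            y=np.array(["room", "cold"] * 30),
        )
        _, ratios = pca_embed(table, 3)
        assert ratios[2] == pytest.approx(0.0, abs=1e-12)

    def test_too_many_components_rejected(self):
        with pytest.raises(ValueError):
            pca_embed(make_blobs_table(), 6)

    def test_full_reconstruction_error_zero(self):
        from sklearn.decomposition import PCA

        table = make_blobs_table(n=50, seed=8)
        pca = PCA(n_components=5).fit(table.X)
        back = pca.inverse_transform(pca.transform(table.X))
        np.testing.assert_allclose(back, table.X, atol=1e-8)


def test_confusion_from_predictions_counts():
    y_true = np.array(["room", "room", "cold", "cold", "room"])
    y_pred = np.array(["room", "cold", "cold", "room", "room"])
    cm = confusion_from_predictions(y_true, y_pred)
    assert (cm.tp, cm.fp, cm.fn, cm.tn) == (2, 1, 1, 1)
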