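import numpy as np
import pytest

from burntex import (
    BinaryConfusion,
    FeatureMatrix,
    MulticlassConfusion,
    SampleSizeSpec,
    compute_measures,
    kfda_classify,
    kfda_fit,
    kfda_transform,
    loocv_binary,
    loocv_multiclass,
    min_sample_size,
    monte_carlo_eval,
    svm_score,
    train_svm,
)


def two_cluster_matrix(left=(0.0, 0.1), right=(0.9, 1.0)):
    vals = np.array(list(left) + list(right), dtype=float).reshape(-1, 1)
    labels = ("L",) * len(left) + ("R",) * len(right)
    return FeatureMatrix(vals, ("f",), labels)


def gaussian_classes(rng, centers, n=12, spread=0.15):
    X, labels = [], []
    for k, c in enumerate(centers):
        X.append(rng.normal(loc=c, scale=spread, size=(n, len(c))))
        labels += [f"c{k}"] * n
    return FeatureMatrix(np.vstack(X), tuple(f"x{d}" for d in range(len(centers[0]))), tuple(labels))


class TestSvm:
    def test_separable_clusters_classified(self):
        m = two_cluster_matrix()
        model = train_svm(m, positive_label="L")
        assert svm_score(model, [0.05]) > 0
        assert svm_score(model, [0.95]) < 0

    def test_duplicated_overlapping_points_no_crash(self):
        vals = np.array([[0.5], [0.5], [0.5], [0.5]])
        m = FeatureMatrix(vals, ("f",), ("A", "A", "B", "B"))
        model = train_svm(m, positive_label="A")
        svm_score(model, [0.5])  # defined, sign unspecified

    def test_xor_pattern_needs_kernel_nonlinearity(self):
        vals = np.array([[0, 0], [1, 1], [0, 1], [1, 0]], dtype=float)
        vals = np.repeat(vals, 2, axis=0) + 0.01 * np.arange(8)[:, None]
        labels = ("A", "A", "A", "A", "B", "B", "B", "B")
        m = FeatureMatrix(vals, ("x", "y"), labels)
        model = train_svm(m, positive_label="A", gamma=10.0, C=100.0)
        preds = [svm_score(model, v) > 0 for v in vals]
        assert preds == [lab == "A" for lab in labels]

    def test_score_is_continuous(self):
        m = two_cluster_matrix()
        model = train_svm(m, positive_label="L")
        deltas = [abs(svm_score(model, [x + 1e-4]) - svm_score(model, [x])) for x in (0.2, 0.5, 0.8)]
        assert max(deltas) < 1e-2

    def test_dimension_mismatch_rejected(self):
        model = train_svm(two_cluster_matrix(), positive_label="L")
        with pytest.raises(ValueError, match="features"):
            svm_score(model, [0.1, 0.2])

    def test_single_class_rejected(self):
        vals = np.zeros((4, 1))
        m = FeatureMatrix(vals, ("f",), ("A",) * 4)
        with pytest.raises(ValueError, match="2 classes"):
            train_svm(m, positive_label="A")


class TestLoocvBinary:
    def test_separated_classes_reach_perfect_accuracy(self, rng):
        m = gaussian_classes(rng, [(0.0, 0.0), (2.0, 2.0)], n=15)
        cm, meas, scores = loocv_binary(m, positive_label="c0")
        assert meas.accuracy == 1.0
        assert cm.total == 30
        assert len(scores) == 30
        # positive-class samples score positive
        assert all(s > 0 for s in scores[:15]) and all(s < 0 for s in scores[15:])

    def test_confusion_total_equals_sample_count(self, rng):
        m = gaussian_classes(rng, [(0.0,), (0.4,)], n=8, spread=0.3)
        cm, _, _ = loocv_binary(m, positive_label="c0")
        assert cm.total == 16

    def test_order_invariance(self, rng):
        m = gaussian_classes(rng, [(0.0, 0.0), (1.2, 1.2)], n=10, spread=0.5)
        perm = rng.permutation(m.n_samples)
        shuffled = FeatureMatrix(
            m.values[perm], m.feature_names,
            tuple(np.asarray(m.labels)[perm]), tuple(np.asarray(m.sample_ids)[perm]),
        )
        cm1, _, _ = loocv_binary(m, positive_label="c0")
        cm2, _, _ = loocv_binary(shuffled, positive_label="c0")
        assert (cm1.tp, cm1.fn, cm1.fp, cm1.tn) == (cm2.tp, cm2.fn, cm2.fp, cm2.tn)

    def test_tiny_class_rejected(self):
        m = FeatureMatrix(np.zeros((3, 1)), ("f",), ("A", "B", "B"))
        with pytest.raises(ValueError, match="at least 2"):
            loocv_binary(m, positive_label="A")


class TestMeasures:
    @pytest.mark.parametrize(
        "cm, expected",
        [
            (BinaryConfusion(33, 0, 0, 37), (1.0, 1.0, 1.0)),
            (BinaryConfusion(36, 3, 2, 35), (71 / 76, 36 / 39, 35 / 37)),
            (BinaryConfusion(0, 5, 0, 5), (0.5, 0.0, 1.0)),
        ],
    )
    def test_ratio_arithmetic(self, cm, expected):
        meas = compute_measures(cm)
        assert (meas.accuracy, meas.sensitivity, meas.specificity) == pytest.approx(expected)

    def test_two_decimal_rounding_is_half_up(self):
        meas = compute_measures(BinaryConfusion(36, 3, 2, 35)).rounded(2)
        assert (meas.accuracy, meas.sensitivity, meas.specificity) == (0.93, 0.92, 0.95)

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            compute_measures(BinaryConfusion(0, 0, 2, 3))

    def test_multiclass_overall_and_per_class(self):
        grid = np.array([[33, 0, 4, 0], [0, 31, 2, 0], [3, 0, 36, 0], [0, 1, 0, 33]])
        cm = MulticlassConfusion(grid, ("i", "ii", "iii", "iv"))
        assert cm.total == 143
        assert cm.overall_accuracy == pytest.approx(133 / 143)
        np.testing.assert_allclose(
            cm.per_class_accuracy, [33 / 37, 31 / 33, 36 / 39, 33 / 34]
        )

    def test_near_diagonal_grid_arithmetic(self):
        grid = np.eye(3, dtype=int) * 10
        grid[0, 1] = 1
        cm = MulticlassConfusion(grid, ("a", "b", "c"))
        assert cm.overall_accuracy == pytest.approx(30 / 31)


class TestKfda:
    def test_two_separable_classes_project_apart(self):
        m = two_cluster_matrix()
        model = kfda_fit(m)
        scores = model.train_scores[:, 0]
        gap = abs(scores[:2].mean() - scores[2:].mean())
        spread = max(scores[:2].std(), scores[2:].std(), 1e-12)
        assert gap > spread

    def test_four_clusters_give_three_discriminants(self, rng):
        m = gaussian_classes(
            rng, [(0, 0), (1.5, 0), (0, 1.5), (1.5, 1.5)], n=8, spread=0.1
        )
        model = kfda_fit(m)
        assert model.alphas.shape[1] == 3
        dists = np.linalg.norm(
            model.centroids[:, None, :] - model.centroids[None, :, :], axis=-1
        )
        assert dists[np.triu_indices(4, 1)].min() > 0.01

    def test_training_centroid_classifies_to_own_label(self, rng):
        m = gaussian_classes(rng, [(0.0, 0.0), (2.0, 2.0)], n=8)
        model = kfda_fit(m)
        for k, lab in enumerate(model.class_labels):
            sample = m.values[np.asarray(m.labels) == lab].mean(axis=0)
            assert kfda_classify(model, sample) == lab

    def test_single_class_rejected(self):
        m = FeatureMatrix(np.zeros((4, 1)), ("f",), ("A",) * 4)
        with pytest.raises(ValueError, match="at least 2 classes"):
            kfda_fit(m)

    def test_transform_reproduces_training_scores(self, rng):
        m = gaussian_classes(rng, [(0.0,), (1.0,)], n=6)
        model = kfda_fit(m)
        np.testing.assert_allclose(
            kfda_transform(model, m.values), model.train_scores, atol=1e-10
        )

    def test_wide_kernel_limit_matches_fisher_lda_axis(self, rng):
        """With a very wide RBF kernel the leading kernel discriminant
        projection correlates almost perfectly with classical LDA scores."""
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        m = gaussian_classes(rng, [(0.0, 0.0), (1.0, 0.5)], n=25, spread=0.4)
        y = np.asarray(m.labels)
        model = kfda_fit(m, gamma=1e-4, regularization=1e-10)
        lda = LinearDiscriminantAnalysis().fit(m.values, y)
        a = model.train_scores[:, 0]
        b = lda.decision_function(m.values)
        corr = abs(np.corrcoef(a, b)[0, 1])
        assert corr > 0.99


class TestLoocvMulticlass:
    def test_perfectly_separated_three_classes(self, rng):
        m = gaussian_classes(rng, [(0, 0), (2, 0), (0, 2)], n=8, spread=0.1)
        cm, per_class, overall = loocv_multiclass(m)
        assert overall == 1.0
        np.testing.assert_array_equal(cm.counts, np.eye(3, dtype=int) * 8)
        np.testing.assert_allclose(per_class, 1.0)

    def test_counts_total_and_order_invariance(self, rng):
        m = gaussian_classes(rng, [(0.0,), (0.6,), (1.2,)], n=6, spread=0.3)
        cm, _, _ = loocv_multiclass(m)
        assert cm.total == 18
        perm = rng.permutation(m.n_samples)
        shuffled = FeatureMatrix(
            m.values[perm], m.feature_names,
            tuple(np.asarray(m.labels)[perm]), tuple(np.asarray(m.sample_ids)[perm]),
        )
        cm2, _, _ = loocv_multiclass(shuffled)
        # same aggregate counts once rows/cols are matched by label
        order = [shuffled.classes.index(c) for c in m.classes]
        np.testing.assert_array_equal(cm.counts, cm2.counts[np.ix_(order, order)])


class TestMonteCarlo:
    def test_separable_single_repetition_is_perfect(self, rng):
        m = gaussian_classes(rng, [(0, 0), (2, 2)], n=10, spread=0.1)
        mean_acc, accs = monte_carlo_eval(m, train_fraction=0.8, repetitions=1, seed=3)
        assert mean_acc == 1.0 and len(accs) == 1

    def test_same_seed_reproduces_accuracies(self, rng):
        m = gaussian_classes(rng, [(0.0,), (0.5,)], n=10, spread=0.3)
        _, a1 = monte_carlo_eval(m, repetitions=5, seed=11)
        _, a2 = monte_carlo_eval(m, repetitions=5, seed=11)
        np.testing.assert_array_equal(a1, a2)

    def test_infeasible_split_rejected(self, rng):
        m = gaussian_classes(rng, [(0.0,), (1.0,)], n=2)
        with pytest.raises(ValueError, match="cannot be split"):
            monte_carlo_eval(m, train_fraction=0.5, repetitions=1, seed=0)


class TestSampleSize:
    def test_reference_case_yields_46(self):
        spec = SampleSizeSpec(0.95, 0.95, prevalence=0.4, margin=0.1, z=1.96)
        assert min_sample_size(spec) == 46

    def test_perfect_test_needs_no_samples(self):
        spec = SampleSizeSpec(1.0, 1.0, prevalence=0.4, margin=0.1, z=1.96)
        assert min_sample_size(spec) == 0

    def test_symmetric_case_ceiling(self):
        spec = SampleSizeSpec(0.9, 0.9, prevalence=0.5, margin=0.1, z=1.96)
        assert min_sample_size(spec) == 70  # 1.96^2 * 0.09 / (0.01 * 0.5) = 69.15

    def test_monotone_in_margin_and_z(self):
        base = dict(sensitivity=0.9, specificity=0.9, prevalence=0.4)
        n_wide = min_sample_size(SampleSizeSpec(margin=0.2, z=1.96, **base))
        n_narrow = min_sample_size(SampleSizeSpec(margin=0.05, z=1.96, **base))
        assert n_narrow >= n_wide
        n_lo = min_sample_size(SampleSizeSpec(margin=0.1, z=1.64, **base))
        n_hi = min_sample_size(SampleSizeSpec(margin=0.1, z=2.58, **base))
        assert n_hi >= n_lo

    def test_degenerate_prevalence_rejected(self):
        with pytest.raises(ValueError, match="prevalence"):
            SampleSizeSpec(0.9, 0.9, prevalence=1.0, margin=0.1)

    def test_from_alpha_matches_explicit_z(self):
        spec = SampleSizeSpec.from_alpha(0.95, 0.95, 0.4, 0.1, alpha=0.05)
        assert spec.z == pytest.approx(1.959964, abs=1e-6)
        assert min_sample_size(spec) == 46
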