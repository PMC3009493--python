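import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from oracles import greedy_decorrelate_reference, recount_selected
from sfssclass import usc
from sfssclass.datatypes import ExpressionMatrix
from sfssclass.synthetic import make_classification_data

# Expected values below were computed independently with exact rational
# arithmetic for the two worked fixtures (see conftest): the 2-feature /
# 4-sample / 2-class matrix and the 2-feature / 6-sample / 3-class matrix.
SQRT2 = np.sqrt(2.0)
SQRT6 = np.sqrt(6.0)


class TestComputeCentroids:
    def test_hand_fixture_statistics(self, two_feature_matrix):
        st_ = usc.compute_centroids(two_feature_matrix)
        assert st_.class_labels == ["A", "B"]
        np.testing.assert_allclose(st_.overall_centroid, [4.0, 4.0], atol=1e-12)
        np.testing.assert_allclose(st_.class_centroids, [[2.0, 6.0], [4.0, 4.0]], atol=1e-12)
        np.testing.assert_allclose(st_.s_i, [SQRT2, 2.0], atol=1e-12)
        assert st_.s_0 == pytest.approx((SQRT2 + 2.0) / 2.0, abs=1e-12)

    def test_constant_feature_has_zero_sd_equal_centroids(self):
        m = ExpressionMatrix(
            ["f"], ["a", "b", "c", "d"], np.full((1, 4), 3.0),
            labels={"a": "A", "b": "A", "c": "B", "d": "B"},
        )
        st_ = usc.compute_centroids(m)
        assert st_.s_i[0] == 0.0
        np.testing.assert_allclose(st_.class_centroids, [[3.0, 3.0]])

    def test_overall_centroid_is_weighted_class_mean(self, rng):
        labels = {f"s{j}": "ABC"[j % 3] for j in range(12)}
        m = ExpressionMatrix(
            [f"g{i}" for i in range(5)], list(labels), rng.normal(size=(5, 12)),
            labels=labels,
        )
        st_ = usc.compute_centroids(m)
        weighted = (st_.class_centroids * st_.n_k).sum(axis=1) / st_.n
        np.testing.assert_allclose(weighted, st_.overall_centroid, atol=1e-12)

    def test_small_class_rejected(self):
        m = ExpressionMatrix(
            ["f"], ["a", "b", "c"], np.zeros((1, 3)),
            labels={"a": "A", "b": "A", "c": "B"},
        )
        with pytest.raises(ValueError, match="fewer than 2"):
            usc.compute_centroids(m)


class TestRelativeDifference:
    def test_single_feature_hand_value(self):
        m = ExpressionMatrix(
            ["f"], ["a", "b", "c", "d"],
            np.array([[1.0, 3.0, 5.0, 7.0]]),
            labels={"a": "A", "b": "A", "c": "B", "d": "B"},
        )
        d = usc.relative_difference(usc.compute_centroids(m))
        # m_k = sqrt(1/2 - 1/4) = 1/2; s_i = s_0 = sqrt(2); d_A = -sqrt(2)
        np.testing.assert_allclose(d, [[-SQRT2, SQRT2]], atol=1e-12)

    def test_zero_gap_gives_zero_and_signs_follow_gaps(self, rng):
        labels = {f"s{j}": "AB"[j % 2] for j in range(10)}
        m = ExpressionMatrix(
            [f"g{i}" for i in range(6)], list(labels), rng.normal(size=(6, 10)),
            labels=labels,
        )
        st_ = usc.compute_centroids(m)
        d = usc.relative_difference(st_)
        gaps = st_.class_centroids - st_.overall_centroid[:, None]
        np.testing.assert_array_equal(np.sign(d), np.sign(gaps))


class TestShrink:
    @pytest.mark.parametrize(
        "d, delta, expected", [(0.9, 0.3, 0.6), (-0.2, 0.3, 0.0), (-0.9, 0.3, -0.6)]
    )
    def test_closed_form(self, d, delta, expected):
        assert usc.shrink(np.array([[d]]), delta)[0, 0] == pytest.approx(expected)

    def test_zero_delta_is_identity(self, rng):
        d = rng.normal(size=(7, 3))
        np.testing.assert_array_equal(usc.shrink(d, 0.0), d)

    def test_negative_delta_rejected(self):
        with pytest.raises(ValueError):
            usc.shrink(np.zeros((1, 1)), -0.1)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        d=arrays(np.float64, (5, 3), elements=st.floats(-5, 5)),
        delta=st.floats(0, 6),
    )
    def test_soft_threshold_contract(self, d, delta):
        dp = usc.shrink(d, delta)
        np.testing.assert_allclose(np.abs(dp), np.maximum(np.abs(d) - delta, 0.0), atol=1e-12)
        assert np.all((dp == 0) | (np.sign(dp) == np.sign(d)))


class TestSelectFeatures:
    def test_monotone_and_matches_recount(self, rng):
        d = rng.normal(scale=1.5, size=(50, 4))
        prev = None
        for delta in np.linspace(0.0, 4.0, 20):
            dp = usc.shrink(d, delta)
            try:
                sel = set(usc.select_features(dp).tolist())
            except usc.EmptyFeatureSetError:
                sel = set()
            assert sel == recount_selected(dp)
            if prev is not None:
                assert sel <= prev
            prev = sel

    def test_all_shrunk_away_is_an_error(self):
        with pytest.raises(usc.EmptyFeatureSetError):
            usc.select_features(np.zeros((4, 2)))


def labeled_matrix(values, classes, rng=None):
    values = np.asarray(values, dtype=float)
    n = values.shape[1]
    labels = {f"s{j}": classes[j] for j in range(n)}
    return ExpressionMatrix(
        [f"g{i:02d}" for i in range(values.shape[0])],
        [f"s{j}" for j in range(n)],
        values,
        labels=labels,
    )


class TestDecorrelate:
    def test_identical_features_keep_the_stronger(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=8)
        vals = np.vstack([base, base, rng.normal(size=8)])
        m = labeled_matrix(vals, "AAAABBBB")
        st_ = usc.compute_centroids(m)
        d = usc.relative_difference(st_)
        sel = np.array([0, 1, 2])
        kept = usc.decorrelate(sel, m, d, rho=0.9)
        strengths = np.abs(d).max(axis=1)
        winner = 0 if strengths[0] >= strengths[1] else 1
        assert winner in kept and {0, 1} - {winner} & set(kept.tolist()) == set()

    def test_rho_one_keeps_everything(self, rng):
        m = labeled_matrix(rng.normal(size=(10, 8)), "AAAABBBB")
        d = usc.relative_difference(usc.compute_centroids(m))
        sel = np.arange(10)
        assert set(usc.decorrelate(sel, m, d, rho=1.0).tolist()) == set(range(10))

    def test_greedy_scan_matches_reference_and_pairwise_bound(self, rng):
        vals = rng.normal(size=(12, 10))
        vals[3] = vals[0] * 0.95 + rng.normal(scale=0.1, size=10)
        vals[7] = -vals[1] + rng.normal(scale=0.05, size=10)
        m = labeled_matrix(vals, "AAAAABBBBB")
        d = usc.relative_difference(usc.compute_centroids(m))
        sel = np.arange(12)
        rho = 0.6
        kept = usc.decorrelate(sel, m, d, rho=rho)
        ref = greedy_decorrelate_reference(
            vals, np.abs(d).max(axis=1), m.feature_ids, rho
        )
        assert kept.tolist() == ref
        cmat = np.abs(np.corrcoef(vals[kept]))
        assert (cmat[~np.eye(len(kept), dtype=bool)] <= rho + 1e-12).all()

    def test_zero_variance_feature_rejected(self):
        vals = np.vstack([np.ones(8), np.random.default_rng(0).normal(size=8)])
        m = labeled_matrix(vals, "AAAABBBB")
        d = np.ones((2, 2))
        with pytest.raises(ValueError, match="zero-variance"):
            usc.decorrelate(np.array([0, 1]), m, d, rho=0.5)


class TestFitAndPredict:
    def test_no_shrinkage_reproduces_class_centroids(self, two_feature_matrix):
        model = usc.fit(two_feature_matrix, delta=0.0, rho=1.0)
        st_ = usc.compute_centroids(two_feature_matrix)
        for i, f in enumerate(model.selected_features):
            src = two_feature_matrix.feature_ids.index(f)
            np.testing.assert_allclose(
                model.shrunken_centroids[i], st_.class_centroids[src], atol=1e-12
            )

    def test_excessive_delta_is_an_error(self, two_feature_matrix):
        with pytest.raises(usc.EmptyFeatureSetError):
            usc.fit(two_feature_matrix, delta=50.0, rho=1.0)

    def test_hand_fixture_shrinkage_path(self, two_feature_matrix):
        # delta = 0.5: feature f1 has |d| = 1.28150896406816 -> d' = +-0.781508964068163
        # feature f2 has d = 0 and is dropped
        model = usc.fit(two_feature_matrix, delta=0.5, rho=1.0)
        assert model.selected_features == ["f1"]
        np.testing.assert_allclose(
            model.shrunken_centroids, [[2.78033008588991, 5.21966991411009]], atol=1e-9
        )

    def test_three_class_hand_scores(self, three_class_matrix):
        model = usc.fit(three_class_matrix, delta=0.5, rho=1.0)
        scores = usc.discriminant_score(np.array([1.0, 4.0]), model)
        np.testing.assert_allclose(
            scores, [2.36389124400289, 4.37230962020569, 8.7725647488141], atol=1e-9
        )
        label, _, tie = usc.predict(np.array([1.0, 4.0]), model)
        assert label == "A" and not tie

    def test_equidistant_sample_ties_to_first_class(self):
        m = labeled_matrix(np.array([[1.0, 3.0, 5.0, 7.0]]), "AABB")
        model = usc.fit(m, delta=0.0, rho=1.0)
        label, scores, tie = usc.predict(np.array([4.0]), model)
        assert tie and label == "A"
        assert scores[0] == pytest.approx(scores[1])

    def test_sample_at_centroid_with_uniform_priors(self, three_class_matrix):
        model = usc.fit(three_class_matrix, delta=0.0, rho=1.0, prior_mode="uniform")
        x = model.shrunken_centroids[:, 1]
        label, scores, _ = usc.predict(x, model)
        assert label == "B"
        assert scores[1] == pytest.approx(-2.0 * np.log(1.0 / 3.0))

    def test_two_class_boundary_is_centroid_midpoint(self):
        m = labeled_matrix(np.array([[0.0, 2.0, 6.0, 8.0]]), "AABB")
        model = usc.fit(m, delta=0.3, rho=1.0, prior_mode="uniform")
        lo, hi = model.shrunken_centroids[0]
        mid = (lo + hi) / 2
        assert usc.predict(np.array([mid - 1e-6]), model)[0] == "A"
        assert usc.predict(np.array([mid + 1e-6]), model)[0] == "B"

    def test_feature_order_invariance(self, rng):
        m, labels, _ = make_classification_data(K=3, p=20, n_k=8, p_info=3, effect=2.0, seed=5)
        perm = rng.permutation(20)
        m2 = ExpressionMatrix(
            [m.feature_ids[i] for i in perm],
            m.sample_ids,
            m.values[perm],
            scale=m.scale,
            labels=m.labels,
        )
        test, _, _ = make_classification_data(K=3, p=20, n_k=4, p_info=3, effect=2.0, seed=6)
        model1 = usc.fit(m, 0.5, 0.9)
        model2 = usc.fit(m2, 0.5, 0.9)
        l1, _, _ = usc.predict_matrix(test, model1)
        l2, _, _ = usc.predict_matrix(test, model2)
        assert l1 == l2

    def test_well_separated_classes_classified_accurately(self):
        train, _, _ = make_classification_data(K=4, p=60, n_k=15, p_info=4, effect=3.0, seed=2)
        test, tlabels, _ = make_classification_data(K=4, p=60, n_k=50, p_info=4, effect=3.0, seed=3)
        model = usc.fit(train, delta=1.0, rho=0.9)
        pred, _, _ = usc.predict_matrix(test, model)
        truth = [tlabels[s] for s in test.sample_ids]
        acc = np.mean([p == t for p, t in zip(pred, truth)])
        assert acc >= 0.95

    def test_sc_equivalence_at_rho_one(self):
        train, _, _ = make_classification_data(K=3, p=40, n_k=10, p_info=4, effect=2.0, seed=9)
        test, _, _ = make_classification_data(K=3, p=40, n_k=10, p_info=4, effect=2.0, seed=10)
        for delta in (0.0, 0.5, 1.0):
            m_usc = usc.fit(train, delta, rho=1.0)
            m_sc = usc.fit(train, delta, rho=1.0, apply_decorrelation=False)
            assert m_usc.selected_features == m_sc.selected_features
            l1, s1, _ = usc.predict_matrix(test, m_usc)
            l2, s2, _ = usc.predict_matrix(test, m_sc)
            assert l1 == l2
            np.testing.assert_allclose(s1, s2, atol=1e-12)

    def test_missing_selected_feature_rejected(self, two_feature_matrix):
        model = usc.fit(two_feature_matrix, 0.0, 1.0)
        bad = ExpressionMatrix(["f1"], ["t1"], np.array([[1.0]]))
        if "f2" in model.selected_features:
            with pytest.raises(ValueError, match="lacks selected features"):
                usc.predict_matrix(bad, model)
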