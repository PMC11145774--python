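"""Classifier configuration, KNN oracle equivalence, Gini/Minkowski utilities."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.ensemble import RandomForestClassifier, StackingClassifier

import bdcfgp as b
from bdcfgp.modeling import ModelConfig, TieBreakKNN, build_model


class TestMinkowski:
    @pytest.mark.parametrize(
        "x,y,p,d",
        [((0, 0), (3, 4), 2, 5.0), ((0, 0), (3, 4), 1, 7.0), ((1, 2), (1, 2), 2, 0.0)],
    )
    def test_known_values(self, x, y, p, d):
        assert b.minkowski_distance(x, y, p) == pytest.approx(d)

    def test_invalid_order_and_shape(self):
        with pytest.raises(ValueError):
            b.minkowski_distance((1,), (2,), p=0.5)
        with pytest.raises(ValueError):
            b.minkowski_distance((1, 2), (1, 2, 3))

    @given(
        st.lists(st.floats(-50, 50), min_size=3, max_size=3),
        st.lists(st.floats(-50, 50), min_size=3, max_size=3),
        st.lists(st.floats(-50, 50), min_size=3, max_size=3),
        st.sampled_from([1, 1.5, 2, 3]),
    )
    @settings(max_examples=100, deadline=None)
    def test_metric_axioms(self, x, y, z, p):
        dxy = b.minkowski_distance(x, y, p)
        assert dxy >= 0
        assert dxy == pytest.approx(b.minkowski_distance(y, x, p))
        assert dxy <= (
            b.minkowski_distance(x, z, p) + b.minkowski_distance(z, y, p) + 1e-9
        )


class TestGini:
    @pytest.mark.parametrize(
        "props,expected",
        [((1.0,), 0.0), ((0.5, 0.5), 0.5), ([1 / 6] * 6, 1 - 6 * (1 / 6) ** 2)],
    )
    def test_known_values(self, props, expected):
        assert b.gini_impurity(props) == pytest.approx(expected)

    def test_rejects_bad_proportions(self):
        with pytest.raises(ValueError):
            b.gini_impurity((0.5, 0.4))
        with pytest.raises(ValueError):
            b.gini_impurity((-0.5, 1.5))

    @pytest.mark.parametrize("k", [2, 3, 4, 5, 6])
    def test_maximized_at_uniform(self, k, rng):
        uniform = b.gini_impurity([1 / k] * k)
        assert uniform == pytest.approx(1 - 1 / k)
        for _ in range(20):
            p = rng.dirichlet(np.ones(k))
            g = b.gini_impurity(p)
            assert 0 <= g <= uniform + 1e-12


class TestBuildModel:
    def test_unknown_name_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig("adaboost")

    def test_pinned_defaults(self):
        rf = build_model(ModelConfig("rf", seed=1))
        assert (rf.n_estimators, rf.min_samples_split, rf.max_depth,
                rf.min_samples_leaf, rf.criterion) == (100, 2, None, 1, "gini")
        knn = build_model(ModelConfig("knn"))
        assert (knn.n_neighbors, knn.metric, knn.p) == (3, "minkowski", 2)
        cnb = build_model(ModelConfig("cnb"))
        assert (cnb.alpha, cnb.fit_prior) == (1.0, True)
        svm = build_model(ModelConfig("svm"))
        assert (svm.kernel, svm.degree, svm.gamma) == ("linear", 3, "scale")
        bag = build_model(ModelConfig("bagging"))
        assert bag.n_estimators == 10
        assert bag.estimator.hidden_layer_sizes == (100,)
        assert bag.estimator.max_iter == 1000

    def test_stacking_has_four_bases_and_rf_meta(self):
        stack = build_model(ModelConfig("stacking"))
        assert isinstance(stack, StackingClassifier)
        assert [n for n, _ in stack.estimators] == ["dt", "rf", "cnb", "knn"]
        assert isinstance(stack.final_estimator, RandomForestClassifier)

    def test_single_class_labels_rejected(self):
        with pytest.raises(ValueError):
            b.build_and_train(ModelConfig("dt"), np.ones((4, 2)), [1, 1, 1, 1])


class TestPredict:
    def test_knn_toy_majority(self):
        X = np.array([[0.0], [1.0], [10.0]])
        y = np.array(["A", "A", "B"])
        model = b.build_and_train(ModelConfig("knn"), X, y)
        assert b.predict(model, np.array([[0.5]]))[0] == "A"

    def test_empty_input_and_dim_mismatch(self):
        model = b.build_and_train(
            ModelConfig("dt"), np.arange(8).reshape(4, 2), [0, 0, 1, 1]
        )
        assert len(b.predict(model, np.empty((0, 2)))) == 0
        with pytest.raises(ValueError):
            b.predict(model, np.ones((2, 3)))

    def test_dt_memorizes_distinct_points(self, rng):
        X = rng.permutation(100).reshape(50, 2).astype(float)
        y = rng.integers(0, 3, size=50)
        y[:3] = [0, 1, 2]
        model = b.build_and_train(ModelConfig("dt"), X, y)
        assert b.accuracy(y, b.predict(model, X)) == 1.0

    def test_knn_matches_brute_force_vote(self, rng):
        # oracle: explicit 3-NN majority with closest-class then lowest-label
        # tie-breaks, on small random ordinal instances
        for trial in range(5):
            # continuous coordinates so the 3-nearest sets are unambiguous
            X = rng.random(size=(40, 4)) * 6
            y = rng.integers(0, 6, size=40)
            if len(np.unique(y)) < 2:
                continue
            Q = rng.random(size=(25, 4)) * 6
            model = b.build_and_train(ModelConfig("knn"), X, y)
            got = b.predict(model, Q)
            for q, g in zip(Q, got):
                d = np.linalg.norm(X - q, axis=1)
                order = np.argsort(d, kind="stable")[:3]
                votes = y[order]
                labs, cnts = np.unique(votes, return_counts=True)
                tied = labs[cnts == cnts.max()]
                sums = [d[order][votes == lab].sum() for lab in tied]
                best = sorted(zip(sums, tied))[0][1]
                assert g == best

    @pytest.mark.parametrize("name", ["rf", "stacking"])
    def test_seeded_ensembles_deterministic(self, name, fgp_frame):
        # full synthetic study table: every class has enough members for the
        # stacking ensemble's internal 5-fold split
        X = fgp_frame[list(b.TARGET_COLUMNS)].to_numpy(float)
        y = fgp_frame["PT"].to_numpy()
        m1 = b.build_and_train(ModelConfig(name, seed=42), X, y)
        m2 = b.build_and_train(ModelConfig(name, seed=42), X, y)
        np.testing.assert_array_equal(b.predict(m1, X), b.predict(m2, X))

    def test_seeded_bagging_deterministic(self, fgp_frame):
        X = fgp_frame[list(b.TARGET_COLUMNS)].to_numpy(float)[:120]
        y = fgp_frame["PT"].to_numpy()[:120]
        over = {"n_estimators": 3, "max_iter": 120}
        m1 = b.build_and_train(ModelConfig("bagging", seed=7, hyperparameters=over), X, y)
        m2 = b.build_and_train(ModelConfig("bagging", seed=7, hyperparameters=over), X, y)
        np.testing.assert_array_equal(b.predict(m1, X), b.predict(m2, X))

    def test_save_load_roundtrip(self, tmp_path, fgp_frame):
        X = fgp_frame[list(b.TARGET_COLUMNS)].to_numpy(float)[:100]
        y = fgp_frame["PT"].to_numpy()[:100]
        model = b.build_and_train(ModelConfig("dt", seed=3), X, y)
        path = tmp_path / "dt.joblib"
        from bdcfgp.modeling import load_model, save_model

        save_model(model, path)
        again = load_model(path)
        assert again.config == model.config
        np.testing.assert_array_equal(b.predict(again, X), b.predict(model, X))
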