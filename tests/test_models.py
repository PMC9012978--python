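"""Model-layer contracts: normalization, clustering, alignment, the four
supervised learners, and the common prediction interface."""

import numpy as np
import pandas as pd
import pytest

from rootclass.models import (DEFAULT_MODEL_SPECS, ModelSpec,
                              PredictionResult, align_clusters, apply_minmax,
                              cluster_kmeans, cluster_pam, default_mtry,
                              fit_minmax, make_model, train_nb, train_rf)

SPEC = {s.name: s for s in DEFAULT_MODEL_SPECS}


class TestMinMax:
    def test_formula_and_extrapolation(self):
        X = np.array([[2.0], [4.0], [6.0]])
        p = fit_minmax(X)
        assert apply_minmax(X, p).ravel() == pytest.approx([0.0, 0.5, 1.0])
        assert apply_minmax(np.array([[8.0]]), p).ravel() == pytest.approx([1.5])

    def test_constant_column_maps_to_zero(self):
        X = np.array([[5.0, 1.0], [5.0, 2.0], [5.0, 3.0]])
        out = apply_minmax(X, fit_minmax(X))
        assert np.all(out[:, 0] == 0.0)

    def test_nan_rejected_naming_columns(self):
        df = pd.DataFrame({"a": [1.0, 2.0], "b": [np.nan, 1.0]})
        with pytest.raises(ValueError, match="b"):
            fit_minmax(df)


class TestClustering:
    def _blobs(self, n=30, d=4, sep=50.0, seed=0):
        rng = np.random.default_rng(seed)
        centers = np.eye(3, d) * sep
        X = np.vstack([rng.normal(c, 1.0, (n, d)) for c in centers])
        truth = np.repeat([0, 1, 2], n)
        return X, truth, centers

    @pytest.mark.parametrize("algo", [cluster_kmeans, cluster_pam])
    def test_well_separated_blobs_recovered_exactly(self, algo):
        X, truth, centers = self._blobs()
        labels = algo(X, k=3, seed=0)
        # brute-force oracle: nearest true center
        oracle = np.argmin(((X[:, None] - centers[None]) ** 2).sum(-1), axis=1)
        mapped = align_clusters(labels, oracle.astype(str),
                                classes=("0", "1", "2"))
        assert np.all(mapped == oracle.astype(str))

    def test_kmeans_k1_centroid_is_mean(self):
        X = np.random.default_rng(1).normal(size=(20, 3))
        labels = cluster_kmeans(X, k=1, seed=0)
        assert np.all(labels == 0)

    def test_pam_medoids_are_data_points(self):
        X, _, _ = self._blobs(n=10)
        labels, medoids = cluster_pam(X, k=3, seed=0, return_medoids=True)
        assert all(0 <= m < len(X) for m in medoids)
        assert len(set(map(int, medoids))) == 3

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValueError):
            cluster_kmeans(np.zeros((2, 2)), k=3)
        with pytest.raises(ValueError):
            cluster_pam(np.zeros((2, 2)), k=3)


class TestAlignClusters:
    def test_renamed_clusters_fully_recovered(self):
        truth = np.array(["B", "T", "TB"] * 10)
        clusters = np.array([2, 0, 1] * 10)
        assert np.all(align_clusters(clusters, truth) == truth)

    def test_single_cluster_maps_to_majority_class(self):
        truth = np.array(["B"] * 6 + ["T"] * 3 + ["TB"])
        mapped = align_clusters(np.zeros(10, int), truth)
        assert np.all(mapped == "B")

    def test_random_labels_agree_about_one_third(self):
        rng = np.random.default_rng(0)
        n = 3000
        truth = rng.choice(["B", "T", "TB"], n)
        clusters = rng.integers(0, 3, n)
        agree = np.mean(align_clusters(clusters, truth) == truth)
        assert agree == pytest.approx(1 / 3, abs=0.05)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            align_clusters([0, 1], ["B"])


class TestSupervised:
    def _separable(self, n=60, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, 2))
        X[: n // 3, 0] += 8
        X[n // 3: 2 * n // 3, 1] += 8
        y = np.array(["B"] * (n // 3) + ["T"] * (n // 3) + ["TB"] * (n // 3))
        return X, y

    def test_rf_separates_linearly_separable_data(self):
        X, y = self._separable()
        m = train_rf(X, y, seed=0)
        pred = [p.predicted_class for p in m.predict(X)]
        assert np.mean(np.array(pred) == y) >= 0.99

    def test_rf_probabilities_are_vote_fractions(self):
        X, y = self._separable()
        m = train_rf(X, y, ntree=500, seed=0)
        proba = m.predict_proba(X[:5])
        votes = proba * 500
        assert np.allclose(votes, np.round(votes), atol=1e-9)
        assert np.allclose(proba.sum(axis=1), 1.0)

    def test_mtry_default_is_floor_sqrt_p(self):
        assert default_mtry(38) == 6

    def test_nb_with_identical_class_conditionals_returns_priors(self):
        rng = np.random.default_rng(2)
        block = rng.normal(size=(40, 3))
        X = np.vstack([block, block, block])
        y = np.array(["B"] * 40 + ["T"] * 40 + ["TB"] * 40)
        m = train_nb(X, y)
        proba = m.predict_proba(block[:10])
        assert np.allclose(proba, 1 / 3, atol=1e-6)

    def test_single_class_labels_rejected(self):
        X = np.zeros((5, 2))
        with pytest.raises(ValueError):
            train_rf(X, np.array(["B"] * 5))

    def test_missing_trait_columns_named_in_error(self):
        X, y = self._separable(n=30)
        df = pd.DataFrame(X, columns=["trait_a", "trait_b"])
        m = train_rf(df, y, seed=0)
        with pytest.raises(ValueError, match="trait_b"):
            m.predict_proba(df.drop(columns="trait_b"))

    @pytest.mark.parametrize("name", ["rf", "nb", "mlp_classic", "mlp_modern"])
    def test_seed_determinism_supervised(self, name):
        X, y = self._separable(n=30, seed=3)
        spec = SPEC[name]
        if name == "mlp_classic":
            spec = ModelSpec(name, dict(spec.hyperparameters, step_limit=500),
                             True)
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = make_model(spec, seed=5).fit(X, y).predict_proba(X)
            b = make_model(spec, seed=5).fit(X, y).predict_proba(X)
        assert np.array_equal(a, b)

    def test_mlp_classic_warns_when_step_limit_reached(self):
        X, y = self._separable(n=30, seed=4)
        spec = ModelSpec("mlp_classic",
                         dict(SPEC["mlp_classic"].hyperparameters,
                              step_limit=5), True)
        with pytest.warns(UserWarning, match="step limit"):
            m = make_model(spec, seed=0).fit(X, y)
        assert np.allclose(m.predict_proba(X).sum(axis=1), 1.0)


class TestUnsupervisedInterface:
    def test_kmeans_model_roundtrip_through_common_interface(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 0.5, (20, 2)),
                       rng.normal(10, 0.5, (20, 2)),
                       rng.normal([0, 10], 0.5, (20, 2))])
        y = np.array(["B"] * 20 + ["T"] * 20 + ["TB"] * 20)
        m = make_model(SPEC["kmeans"], seed=0).fit(X)
        aligned = m.align(y)
        assert np.mean(aligned == y) == 1.0
        preds = m.predict(X)
        assert all(p.max_probability == 1.0 for p in preds)

    @pytest.mark.parametrize("name", ["kmeans", "pam"])
    def test_seed_determinism_unsupervised(self, name):
        X = np.random.default_rng(7).normal(size=(30, 4))
        a = make_model(SPEC[name], seed=3).fit(X).cluster_labels_
        b = make_model(SPEC[name], seed=3).fit(X).cluster_labels_
        assert np.array_equal(a, b)


class TestPredictionResult:
    def test_argmax_and_max_probability(self):
        p = PredictionResult((0.346, 0.335, 0.319))
        assert p.predicted_class == "B" and p.max_probability == 0.346
        p = PredictionResult((0.005, 0.990, 0.005))
        assert p.predicted_class == "T" and p.max_probability == 0.990

    def test_exact_tie_breaks_in_class_order(self):
        p = PredictionResult((1 / 3, 1 / 3, 1 / 3))
        assert p.predicted_class == "B"

    def test_invalid_probabilities_rejected(self):
        with pytest.raises(ValueError):
            PredictionResult((0.6, 0.6, 0.6))
        with pytest.raises(ValueError):
            PredictionResult((-0.1, 0.6, 0.5))
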