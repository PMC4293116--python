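"""Nearest-shrunken-centroid training, prediction and LOOCV threshold search."""

import numpy as np
import pandas as pd
import pytest

from prognosig.containers import ExpressionMatrix
from prognosig.nsc import (
    loocv_select_threshold,
    predict_nsc,
    signature_genes,
    train_nsc,
)


def as_matrix(X, prefix="s"):
    return ExpressionMatrix(
        pd.DataFrame(
            X,
            index=[f"g{i}" for i in range(X.shape[0])],
            columns=[f"{prefix}{i}" for i in range(X.shape[1])],
        )
    )


def brute_force_scores(model, X):
    """Direct evaluation of the discriminant formula, no vectorisation."""
    G, n = X.shape
    scores = np.zeros((n, len(model.classes)))
    for j in range(n):
        for k in range(len(model.classes)):
            acc = 0.0
            for i in range(G):
                num = (X[i, j] - model.shrunken_centroids[i, k]) ** 2
                acc += num / (model.s[i] + model.s0) ** 2
            scores[j, k] = acc - 2.0 * np.log(model.priors[k])
    return scores


def hand_fixture():
    vals = pd.DataFrame(
        [[0.0, 2.0, 4.0, 6.0], [1.0, 1.0, 1.0, 1.0]],
        index=["g1", "g2"],
        columns=list("abcd"),
    )
    labels = pd.Series(["c1", "c1", "c2", "c2"], index=list("abcd"))
    return ExpressionMatrix(vals), labels


class TestTrain:
    def test_hand_computed_shrinkage(self):
        """Worked 2-gene fixture: s=(sqrt2, 0), s0=0.707, m_k=0.866,
        d_11=-1.089, shrunken centroid 1.918 at delta=0.5."""
        X, labels = hand_fixture()
        m = train_nsc(X, labels, 0.5, classes=["c1", "c2"])
        assert m.s[0] == pytest.approx(np.sqrt(2))
        assert m.s0 == pytest.approx(np.sqrt(2) / 2)
        assert m.m_k[0] == pytest.approx(np.sqrt(0.75))
        assert m.dik[0, 0] == pytest.approx(-1.0886621, abs=1e-6)
        assert m.shrunken_centroids[0, 0] == pytest.approx(1.9185587, abs=1e-6)

    def test_zero_delta_keeps_raw_centroids(self, rng):
        X = as_matrix(rng.normal(size=(10, 12)))
        labels = pd.Series(["a"] * 6 + ["b"] * 6, index=X.sample_ids)
        m = train_nsc(X, labels, 0.0)
        assert np.allclose(m.shrunken_centroids, m.centroids)
        assert signature_genes(m) == list(X.gene_ids)

    def test_full_shrinkage_collapses_to_overall(self, rng):
        X = as_matrix(rng.normal(size=(8, 10)))
        labels = pd.Series(["a"] * 5 + ["b"] * 5, index=X.sample_ids)
        m0 = train_nsc(X, labels, 0.0)
        m = train_nsc(X, labels, float(np.abs(m0.dik).max()))
        assert np.allclose(m.shrunken_centroids, m.overall_centroid[:, None])
        assert signature_genes(m) == []

    def test_small_class_rejected(self, rng):
        X = as_matrix(rng.normal(size=(5, 5)))
        labels = pd.Series(["a"] * 4 + ["b"], index=X.sample_ids)
        with pytest.raises(ValueError, match="fewer than 2"):
            train_nsc(X, labels, 0.0)

    def test_negative_delta_rejected(self):
        X, labels = hand_fixture()
        with pytest.raises(ValueError, match="delta"):
            train_nsc(X, labels, -0.1)

    def test_monotone_sparsity_in_delta(self, rng):
        X = as_matrix(rng.normal(size=(30, 16)))
        labels = pd.Series(["a"] * 8 + ["b"] * 8, index=X.sample_ids)
        m0 = train_nsc(X, labels, 0.0)
        sizes = [
            len(signature_genes(train_nsc(X, labels, d)))
            for d in np.linspace(0, np.abs(m0.dik).max(), 12)
        ]
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))
        assert sizes[0] == 30 and sizes[-1] == 0


class TestPredict:
    def test_oracle_equivalence_random_instances(self, rng):
        for _ in range(10):
            G, n = rng.integers(5, 20), rng.integers(6, 30)
            X = as_matrix(rng.normal(size=(G, n)))
            k = n // 2
            labels = pd.Series(["a"] * k + ["b"] * (n - k), index=X.sample_ids)
            m = train_nsc(X, labels, float(rng.uniform(0, 1.5)))
            Xtest = as_matrix(rng.normal(size=(G, 7)), prefix="t")
            pred, scores = predict_nsc(m, Xtest)
            ref = brute_force_scores(m, Xtest.values.to_numpy())
            assert np.allclose(scores.to_numpy(), ref, atol=1e-10)
            assert (pred.to_numpy() == np.array(m.classes)[ref.argmin(1)]).all()

    def test_sample_at_centroid_wins_with_equal_priors(self):
        X, labels = hand_fixture()
        m = train_nsc(X, labels, 0.2, uniform_priors=True)
        probe = ExpressionMatrix(
            pd.DataFrame(m.shrunken_centroids[:, [1]], index=m.genes, columns=["p0"])
        )
        pred, _ = predict_nsc(m, probe)
        assert pred.iloc[0] == "c2"

    def test_fully_shrunk_predicts_max_prior_class(self, rng):
        X = as_matrix(rng.normal(size=(6, 10)))
        labels = pd.Series(["a"] * 7 + ["b"] * 3, index=X.sample_ids)
        m0 = train_nsc(X, labels, 0.0)
        m = train_nsc(X, labels, float(np.abs(m0.dik).max() + 1))
        pred, _ = predict_nsc(m, X)
        assert (pred == "a").all()

    def test_tie_breaks_toward_first_class(self):
        X, labels = hand_fixture()
        m = train_nsc(X, labels, 0.0, uniform_priors=True, classes=["c1", "c2"])
        midpoint = ExpressionMatrix(
            pd.DataFrame(
                m.shrunken_centroids.mean(axis=1, keepdims=True),
                index=m.genes,
                columns=["p0"],
            )
        )
        pred, scores = predict_nsc(m, midpoint)
        assert scores.iloc[0, 0] == pytest.approx(scores.iloc[0, 1], abs=1e-12)
        assert pred.iloc[0] == "c1"

    def test_common_scaling_of_all_genes_preserves_predictions(self, rng):
        X = as_matrix(rng.normal(size=(12, 20)))
        labels = pd.Series(["a"] * 10 + ["b"] * 10, index=X.sample_ids)
        m1 = train_nsc(X, labels, 0.4)
        X2 = ExpressionMatrix(X.values * 3.0, X.cohort)
        m2 = train_nsc(X2, labels, 0.4)
        t = as_matrix(rng.normal(size=(12, 9)), "t")
        t2 = ExpressionMatrix(t.values * 3.0, t.cohort)
        p1, _ = predict_nsc(m1, t)
        p2, _ = predict_nsc(m2, t2)
        assert (p1.to_numpy() == p2.to_numpy()).all()

    def test_no_gene_overlap_rejected(self, rng):
        X = as_matrix(rng.normal(size=(4, 8)))
        labels = pd.Series(["a"] * 4 + ["b"] * 4, index=X.sample_ids)
        m = train_nsc(X, labels, 0.0)
        other = ExpressionMatrix(
            pd.DataFrame(np.zeros((2, 3)), index=["h1", "h2"], columns=["x", "y", "z"])
        )
        with pytest.raises(KeyError, match="overlap"):
            predict_nsc(m, other)


class TestLOOCV:
    def test_separable_classes_zero_error_largest_delta(self, rng):
        base = rng.normal(size=(10, 1))
        a = base + rng.normal(0, 0.05, (10, 6))
        b = base + 4.0 + rng.normal(0, 0.05, (10, 6))
        X = as_matrix(np.hstack([a, b]))
        labels = pd.Series(["a"] * 6 + ["b"] * 6, index=X.sample_ids)
        profile, model = loocv_select_threshold(X, labels, grid_size=20)
        assert profile.errors.min() == 0
        zero_idx = np.nonzero(profile.errors == 0)[0]
        assert profile.selected_delta == pytest.approx(profile.deltas[zero_idx.max()])

    def test_matches_brute_force_loocv(self, rng):
        """Error curve equals a naive per-fold, per-delta refit loop."""
        X = as_matrix(rng.normal(size=(8, 10)))
        labels = pd.Series(["a"] * 5 + ["b"] * 5, index=X.sample_ids)
        profile, _ = loocv_select_threshold(X, labels, grid_size=8)
        ref = np.zeros(8)
        full = train_nsc(X, labels, 0.0)
        deltas = np.linspace(0, np.abs(full.dik).max(), 8)
        for i, sid in enumerate(X.sample_ids):
            rest = [s for s in X.sample_ids if s != sid]
            Xtr = X.subset_samples(rest)
            for d_idx, d in enumerate(deltas):
                m = train_nsc(Xtr, labels[rest], float(d))
                pred, _ = predict_nsc(m, X.subset_samples([sid]))
                ref[d_idx] += pred.iloc[0] != labels[sid]
        assert np.array_equal(profile.errors, ref)

    def test_permuted_labels_error_near_chance(self):
        """With random balanced labels the best LOOCV error sits around
        chance, tilted pessimistic: leaving out a sample makes its class
        the training minority, so no systematic learning is possible.
        Bounds frozen from this Monte-Carlo oracle."""
        rates = []
        for seed in range(10):
            r = np.random.default_rng(seed)
            X = as_matrix(r.normal(size=(15, 24)))
            lab = pd.Series(
                r.permutation(["a"] * 12 + ["b"] * 12), index=X.sample_ids
            )
            profile, _ = loocv_select_threshold(X, lab, grid_size=10)
            rates.append(profile.errors.min() / profile.n_folds)
        assert 0.35 <= np.mean(rates) <= 0.8

    def test_too_few_samples_rejected(self, rng):
        X = as_matrix(rng.normal(size=(3, 3)))
        labels = pd.Series(["a", "a", "b"], index=X.sample_ids)
        with pytest.raises(ValueError):
            loocv_select_threshold(X, labels)


def test_json_round_trip(tmp_path, rng):
    X = as_matrix(rng.normal(size=(6, 10)))
    labels = pd.Series(["a"] * 5 + ["b"] * 5, index=X.sample_ids)
    m = train_nsc(X, labels, 0.3)
    path = tmp_path / "model.json"
    m.to_json(path)
    from prognosig.nsc import ShrunkenCentroidModel

    back = ShrunkenCentroidModel.from_json(path)
    assert back.classes == m.classes and back.genes == m.genes
    assert np.allclose(back.shrunken_centroids, m.shrunken_centroids)
    t = as_matrix(rng.normal(size=(6, 4)), "t")
    p1, s1 = predict_nsc(m, t)
    p2, s2 = predict_nsc(back, t)
    assert (p1 == p2).all() and np.allclose(s1, s2)
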