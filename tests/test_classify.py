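"""ROC/AUC, cross-validation, the resampling ensemble, importance and
candidate calling."""

import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

import cancerlnc as cl
from cancerlnc import (
    NegativeResamplingEnsemble,
    ValidationError,
    crossval_auc,
    predict_candidates,
    roc_auc,
)
from cancerlnc.classify import predictions_to_dataframe
from cancerlnc.features import FeatureTable


def _table_from_array(X, prefix="g"):
    ids = [f"{prefix}{i}" for i in range(X.shape[0])]
    cols = [f"f{j}" for j in range(X.shape[1])]
    values = pd.DataFrame(X, index=ids, columns=cols)
    mask = pd.DataFrame(False, index=ids, columns=cols)
    return FeatureTable(values, mask, {c: "genomic" for c in cols}), ids


class TestRocAuc:
    def test_perfect_and_inverted(self):
        labels = [1, 1, 0, 0]
        assert roc_auc([0.9, 0.8, 0.2, 0.1], labels) == 1.0
        assert roc_auc([0.1, 0.2, 0.8, 0.9], labels) == 0.0

    def test_concordant_pair_example(self):
        # 3 of 4 positive/negative pairs concordant
        assert roc_auc([0.9, 0.8, 0.7, 0.6], [1, 0, 1, 0]) == pytest.approx(0.75)

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            roc_auc([0.1, 0.2], [1, 1])

    def test_complement_symmetry(self, rng):
        scores = rng.normal(size=40)
        labels = rng.integers(0, 2, size=40)
        labels[0], labels[1] = 0, 1
        assert roc_auc(scores, labels) == pytest.approx(
            1.0 - roc_auc(scores, 1 - labels)
        )

    def test_equals_mann_whitney_u_oracle(self, rng):
        # ties included: scores drawn from a small discrete set
        for _ in range(1000):
            n1, n0 = int(rng.integers(1, 12)), int(rng.integers(1, 12))
            scores = np.concatenate(
                [rng.integers(0, 6, size=n1), rng.integers(0, 6, size=n0)]
            ).astype(float)
            labels = np.array([1] * n1 + [0] * n0)
            pos, neg = scores[:n1], scores[n1:]
            u = sum(
                1.0 if p > q else 0.5 if p == q else 0.0
                for p in pos for q in neg
            )
            assert roc_auc(scores, labels) == pytest.approx(
                u / (n1 * n0), abs=1e-12
            )


class TestCrossvalAuc:
    def test_perfect_feature_gives_auc_one(self, rng):
        X = rng.normal(size=(60, 5))
        X[:30, 0] += 10.0  # a single perfectly separating feature
        table, ids = _table_from_array(X)
        auc = crossval_auc(table, ids[:30], ids[30:], "rf", k=5, seed=0,
                           params={"n_estimators": 50})
        assert auc == 1.0

    def test_null_labels_near_half(self):
        # a fresh noise dataset per seed: pooled out-of-fold AUC averages
        # to chance level across datasets
        aucs = []
        for s in range(10):
            local = np.random.default_rng(s)
            X = local.normal(size=(80, 10))
            table, ids = _table_from_array(X)
            aucs.append(crossval_auc(table, ids[:40], ids[40:], "lr", k=5, seed=s))
        assert abs(np.mean(aucs) - 0.5) < 0.1

    def test_seed_determinism(self, rng):
        X = rng.normal(size=(40, 6))
        X[:20, 1] += 1.0
        table, ids = _table_from_array(X)
        kwargs = dict(k=5, params={"n_estimators": 50})
        a = crossval_auc(table, ids[:20], ids[20:], "rf", seed=3, **kwargs)
        b = crossval_auc(table, ids[:20], ids[20:], "rf", seed=3, **kwargs)
        assert a == b

    def test_class_smaller_than_k_rejected(self, rng):
        X = rng.normal(size=(12, 3))
        table, ids = _table_from_array(X)
        with pytest.raises(ValidationError):
            crossval_auc(table, ids[:5], ids[5:], "rf", k=10)

    @pytest.mark.parametrize("algo", ["nb", "svm", "lr", "knn"])
    def test_all_algorithms_run(self, algo, rng):
        X = rng.normal(size=(60, 5))
        X[:30, 0] += 3.0
        table, ids = _table_from_array(X)
        auc = crossval_auc(table, ids[:30], ids[30:], algo, k=5, seed=0)
        assert auc > 0.9


class TestPooledRocPoints:
    def test_curve_is_monotone_and_anchored(self, rng):
        X = rng.normal(size=(60, 5))
        X[:30, 0] += 2.0
        table, ids = _table_from_array(X)
        sets = [ids[30:50], ids[40:60]]
        roc = cl.pooled_roc_points(table, ids[:30], sets, "nb", k=5, seed=0)
        fpr, tpr = roc["fpr"].to_numpy(), roc["tpr"].to_numpy()
        assert np.all(np.diff(fpr) >= 0) and np.all(np.diff(tpr) >= 0)
        assert fpr[-1] == 1.0 and tpr[-1] == 1.0
        # trapezoidal area over the pooled points is a valid AUC
        assert 0.8 < np.trapezoid(tpr, fpr) <= 1.0


class TestEvaluateAlgorithms:
    def test_single_set_mean_equals_that_set(self, rng):
        X = rng.normal(size=(50, 4))
        X[:25, 0] += 2.0
        table, ids = _table_from_array(X)
        reports = cl.evaluate_algorithms(
            table, ids[:25], [ids[25:]], algorithms=["nb"], k=5, seed=1
        )
        rep = reports["nb"]
        assert len(rep.per_set_auc) == 1
        assert rep.mean_auc == rep.per_set_auc[0]

    def test_category_restriction_uses_only_those_columns(self, rng):
        X = rng.normal(size=(60, 4))
        X[:30, 0] += 5.0  # signal lives in a "genomic" column
        ids = [f"g{i}" for i in range(60)]
        cols = ["f0", "f1", "f2", "f3"]
        cats = {"f0": "genomic", "f1": "genomic", "f2": "network", "f3": "network"}
        table = FeatureTable(
            pd.DataFrame(X, index=ids, columns=cols),
            pd.DataFrame(False, index=ids, columns=cols),
            cats,
        )
        rep = cl.evaluate_algorithms(
            table, ids[:30], [ids[30:]], algorithms=["nb"], k=5, seed=0,
            categories=["network"],
        )
        assert abs(rep["nb"].mean_auc - 0.5) < 0.25  # no signal in network cols
        rep2 = cl.evaluate_algorithms(
            table, ids[:30], [ids[30:]], algorithms=["nb"], k=5, seed=0,
            categories=["genomic"],
        )
        assert rep2["nb"].mean_auc > 0.95


class TestImportance:
    def test_planted_single_feature_ranks_first(self, rng):
        hits = 0
        for s in range(10):
            local = np.random.default_rng(s)
            X = local.normal(size=(80, 12))
            X[:40, 7] += 2.0
            table, ids = _table_from_array(X)
            rep = cl.feature_importance(table, ids[:40], [ids[40:]],
                                        n_trees=100, seed=s)
            if rep.table.iloc[0]["feature"] == "f7":
                hits += 1
        assert hits >= 9

    def test_importances_sum_to_one_and_sorted(self, rng):
        X = rng.normal(size=(40, 8))
        X[:20, 2] += 1.0
        table, ids = _table_from_array(X)
        rep = cl.feature_importance(table, ids[:20], [ids[20:]], n_trees=50, seed=0)
        imp = rep.table["importance"].to_numpy()
        assert imp.sum() == pytest.approx(1.0)
        assert np.all(np.diff(imp) <= 1e-12)

    def test_noise_features_occupy_flat_tail(self, rng):
        X = rng.normal(size=(100, 20))
        X[:50, 0] += 3.0
        table, ids = _table_from_array(X)
        rep = cl.feature_importance(table, ids[:50], [ids[50:]], n_trees=100, seed=1)
        tail = rep.table.iloc[1:]["importance"].to_numpy()
        assert rep.table.iloc[0]["feature"] == "f0"
        assert tail.max() < 0.5 * rep.table.iloc[0]["importance"]
        assert tail.std() < tail.mean()  # near-uniform small values


class TestEnsembleEstimator:
    def test_sklearn_api_fit_predict_clone(self, rng):
        X = rng.normal(size=(120, 6))
        y = np.zeros(120, dtype=int)
        y[:30] = 1
        X[y == 1, 0] += 3.0
        est = NegativeResamplingEnsemble(
            algorithm="rf", n_sets=5, set_size=30,
            params={"n_estimators": 30}, random_state=0,
        )
        cloned = clone(est)  # must round-trip get_params/set_params
        cloned.fit(X, y)
        assert len(cloned.estimators_) == 5
        assert cloned.n_features_in_ == 6
        proba = cloned.predict_proba(X)
        assert proba.shape == (120, 2)
        assert np.allclose(proba.sum(axis=1), 1.0)
        assert roc_auc(proba[:, 1], y) > 0.9
        assert set(cloned.predict(X)) <= {0, 1}

    def test_resampling_is_seeded(self, rng):
        X = rng.normal(size=(60, 4))
        y = np.zeros(60, dtype=int)
        y[:20] = 1
        kw = dict(algorithm="nb", n_sets=3, set_size=20)
        a = NegativeResamplingEnsemble(random_state=1, **kw).fit(X, y)
        b = NegativeResamplingEnsemble(random_state=1, **kw).fit(X, y)
        assert all(np.array_equal(s, t) for s, t in zip(a.sets_idx_, b.sets_idx_))

    def test_oversized_set_rejected(self, rng):
        X = rng.normal(size=(30, 3))
        y = np.zeros(30, dtype=int)
        y[:10] = 1
        est = NegativeResamplingEnsemble(n_sets=2, set_size=50)
        with pytest.raises(ValidationError):
            est.fit(X, y)


class TestPredictCandidates:
    def _setup(self, rng):
        X = rng.normal(size=(140, 6))
        X[:40, 0] += 3.0   # positives
        X[100:120, 0] += 3.0  # positive-like unknowns
        table, ids = _table_from_array(X)
        positives = ids[:40]
        sets = [ids[40 + 10 * i : 40 + 10 * i + 30] for i in range(3)]
        unknowns = ids[100:140]
        return table, positives, sets, unknowns

    def test_ensemble_recovers_positive_like_unknowns(self, rng):
        table, pos, sets, unknowns = self._setup(rng)
        res = predict_candidates(table, pos, sets, unknowns, seed=0,
                                 params={"n_estimators": 50})
        df = predictions_to_dataframe(res).set_index("gene_id")
        assert (df.loc[unknowns[:20], "mean_probability"] > 0.5).mean() >= 0.9
        assert (df["n_models"] == 3).all()

    def test_threshold_one_yields_no_candidates(self, rng):
        table, pos, sets, unknowns = self._setup(rng)
        res = predict_candidates(table, pos, sets, unknowns, threshold=1.0,
                                 seed=0, params={"n_estimators": 20})
        assert not any(r.is_candidate for r in res)

    def test_single_best_mode(self, rng):
        table, pos, sets, unknowns = self._setup(rng)
        res = predict_candidates(table, pos, sets, unknowns, mode="single_best",
                                 seed=0, k=5, params={"n_estimators": 20})
        assert all(r.n_models == 1 for r in res)

    def test_overlap_with_training_rejected(self, rng):
        table, pos, sets, unknowns = self._setup(rng)
        with pytest.raises(ValidationError):
            predict_candidates(table, pos, sets, [pos[0]], seed=0)

    def test_empty_unknowns_empty_result(self, rng):
        table, pos, sets, _ = self._setup(rng)
        assert predict_candidates(table, pos, sets, []) == []
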