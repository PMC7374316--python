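import numpy as np
import pandas as pd
import pytest

from epsm.errors import EpsmError
from epsm.features import feature_columns
from epsm.models import (
    ClassifierSpec,
    EnsembleOfPSMs,
    align_scores,
    compute_baseline_features,
    compute_baseline_weights,
    compute_kappa_weights,
    compute_pairwise_kappa_matrix,
    fit_epsm,
    fit_pim,
    fit_psm,
    predict_known_user,
    predict_unknown_user,
)


class StubMember:
    """A fixed score table standing in for a fitted classifier."""

    def __init__(self, classes, scores):
        self.classes_ = np.asarray(classes, dtype=object)
        self._scores = np.atleast_2d(np.asarray(scores, dtype=float))

    def predict_scores(self, features):
        return self._scores[:len(features)]

    def predict(self, features):
        return self.classes_[np.argmax(self.predict_scores(features),
                                       axis=1)]


def stub_ensemble(members, classes=None):
    classes = classes if classes is not None else sorted(
        {c for m in members.values() for c in m.classes_})
    return EnsembleOfPSMs(
        members=members,
        global_classes=np.asarray(classes, dtype=object))


class TestClassifierSpec:
    def test_reference_hyperparameters(self):
        assert ClassifierSpec("logreg").resolved_hyperparameters() == \
            {"C": 0.98}
        assert ClassifierSpec("knn").resolved_hyperparameters() == \
            {"n_neighbors": 2, "weights": "distance"}
        assert ClassifierSpec("svm").resolved_hyperparameters() == \
            {"gamma": 0.001, "C": 316.0}
        assert ClassifierSpec("gbt").resolved_hyperparameters() == \
            {"learning_rate": 0.02, "n_estimators": 750}

    def test_overrides_merge(self):
        spec = ClassifierSpec("logreg", {"C": 2.0})
        assert spec.resolved_hyperparameters() == {"C": 2.0}

    def test_unknown_algorithm_rejected(self):
        with pytest.raises(EpsmError):
            ClassifierSpec("mlp").resolved_hyperparameters()


class TestProbabilisticContract:
    @pytest.mark.parametrize("algorithm", ["logreg", "knn"])
    def test_scores_sum_to_one_over_sorted_inventory(self, algorithm,
                                                     small_matrix):
        sub = small_matrix[small_matrix["user"] == "user00"]
        model = fit_psm(sub, ClassifierSpec(algorithm), seed=0)
        assert list(model.classes_) == sorted(sub["label"].unique())
        X = sub[feature_columns(sub)].to_numpy()[:20]
        scores = model.predict_scores(X)
        assert scores.min() >= 0
        np.testing.assert_allclose(scores.sum(axis=1), 1.0, atol=1e-9)

    def test_pim_pools_users(self, small_matrix):
        model = fit_pim(small_matrix, ClassifierSpec("logreg"), seed=0)
        assert list(model.classes_) == sorted(small_matrix["label"].unique())

    def test_pim_rejects_single_class(self, small_matrix):
        sub = small_matrix[small_matrix["label"] == "walking"]
        with pytest.raises(EpsmError, match="two classes"):
            fit_pim(sub, ClassifierSpec("logreg"))

    def test_empty_matrix_rejected(self, small_matrix):
        with pytest.raises(EpsmError):
            fit_pim(small_matrix.iloc[:0], ClassifierSpec("logreg"))


class TestAlignScores:
    def test_missing_class_gets_exact_zero(self):
        out = align_scores([[0.7, 0.3]], ["A", "B"], ["A", "B", "C"])
        np.testing.assert_array_equal(out, [[0.7, 0.3, 0.0]])

    def test_identity_when_inventories_match(self):
        out = align_scores([[0.2, 0.5, 0.3]], ["A", "B", "C"],
                           ["A", "B", "C"])
        np.testing.assert_array_equal(out, [[0.2, 0.5, 0.3]])

    def test_single_class_member(self):
        out = align_scores([[1.0]], ["C"], ["A", "B", "C"])
        np.testing.assert_array_equal(out, [[0.0, 0.0, 1.0]])

    def test_foreign_member_class_rejected(self):
        with pytest.raises(EpsmError, match="global inventory"):
            align_scores([[1.0]], ["D"], ["A", "B", "C"])


class TestPredictUnknownUser:
    def test_uniform_mean_scores(self):
        ens = stub_ensemble({
            "u1": StubMember(["A", "B"], [[0.8, 0.2]]),
            "u2": StubMember(["A", "B"], [[0.4, 0.6]])})
        labels, scores = predict_unknown_user(ens, "t", np.zeros((1, 1)),
                                              return_scores=True)
        np.testing.assert_allclose(scores, [[0.6, 0.4]])
        assert labels[0] == "A"

    def test_weighted_tie_breaks_to_first_sorted_class(self):
        ens = stub_ensemble({
            "u1": StubMember(["A", "B"], [[0.8, 0.2]]),
            "u2": StubMember(["A", "B"], [[0.4, 0.6]])})
        ens.weight_table["t"] = np.array([0.25, 0.75])
        labels, scores = predict_unknown_user(ens, "t", np.zeros((1, 1)),
                                              return_scores=True)
        np.testing.assert_allclose(scores, [[0.5, 0.5]])
        assert labels[0] == "A"

    def test_matches_brute_force_weighted_sum(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            n_members = int(rng.integers(2, 6))
            n_classes = int(rng.integers(2, 5))
            n_rows = 20
            global_classes = [f"c{i}" for i in range(n_classes)]
            members, tables = {}, {}
            for m in range(n_members):
                k = int(rng.integers(1, n_classes + 1))
                classes = sorted(rng.choice(global_classes, size=k,
                                            replace=False))
                raw = rng.random((n_rows, k)) + 1e-9
                scores = raw / raw.sum(axis=1, keepdims=True)
                members[f"m{m}"] = StubMember(classes, scores)
                tables[f"m{m}"] = (classes, scores)
            ens = stub_ensemble(members, global_classes)
            w = rng.random(n_members)
            w /= w.sum()
            ens.weight_table["t"] = w
            labels, agg = predict_unknown_user(
                ens, "t", np.zeros((n_rows, 1)), return_scores=True)
            # oracle: independent dense weighted sum over the score tables
            expected = np.zeros((n_rows, n_classes))
            for wi, (classes, scores) in zip(w, tables.values()):
                for j, c in enumerate(classes):
                    expected[:, global_classes.index(c)] += \
                        wi * scores[:, j]
            np.testing.assert_allclose(agg, expected, atol=1e-12)
            np.testing.assert_allclose(agg.sum(axis=1), 1.0, atol=1e-9)
            expected_labels = [global_classes[i]
                               for i in expected.argmax(axis=1)]
            assert list(labels) == expected_labels

    def test_zero_weights_fall_back_to_uniform(self):
        ens = stub_ensemble({
            "u1": StubMember(["A", "B"], [[0.8, 0.2]]),
            "u2": StubMember(["A", "B"], [[0.4, 0.6]])})
        ens.weight_table["t"] = np.zeros(2)
        _, scores = predict_unknown_user(ens, "t", np.zeros((1, 1)),
                                         return_scores=True)
        np.testing.assert_allclose(scores, [[0.6, 0.4]])


class TestKnownUserIdentity:
    def test_known_user_equals_standalone_psm(self, small_matrix):
        per_user = {u: small_matrix[small_matrix["user"] == u]
                    for u in sorted(small_matrix["user"].unique())}
        ens = fit_epsm(per_user, ClassifierSpec("logreg"), seed=0)
        cols = feature_columns(small_matrix)
        for u, sub in per_user.items():
            X = sub[cols].to_numpy()
            standalone = fit_psm(sub, ClassifierSpec("logreg"), seed=0)
            np.testing.assert_array_equal(
                predict_known_user(ens, u, X), standalone.predict(X))

    def test_unknown_user_rejected_by_known_dispatch(self, small_matrix):
        per_user = {u: small_matrix[small_matrix["user"] == u]
                    for u in sorted(small_matrix["user"].unique())[:2]}
        ens = fit_epsm(per_user, ClassifierSpec("logreg"), seed=0)
        with pytest.raises(EpsmError):
            predict_known_user(ens, "ghost", np.zeros((1, 56)))

    def test_member_lacking_class_keeps_global_inventory(self,
                                                         small_matrix):
        users = sorted(small_matrix["user"].unique())
        per_user = {u: small_matrix[small_matrix["user"] == u]
                    for u in users[:2]}
        # strip one activity from the first user
        u0 = users[0]
        per_user[u0] = per_user[u0][per_user[u0]["label"] != "running"]
        ens = fit_epsm(per_user, ClassifierSpec("logreg"), seed=0)
        assert "running" not in ens.members[u0].classes_
        assert "running" in ens.global_classes


class TestPairwiseKappaMatrix:
    def test_perfect_transfer_scores_one(self):
        # three users with identical, linearly separable data: every PSM
        # predicts every other user's labels perfectly -> K[u, v] = 1
        rng = np.random.default_rng(0)
        def frame(user):
            rows = []
            for lab, centre in (("A", -5.0), ("B", 5.0)):
                for i in range(20):
                    rows.append({"user": user, "trial": f"{user}{lab}",
                                 "label": lab,
                                 "f0": centre + rng.normal(0, 0.1)})
            return pd.DataFrame(rows)
        per_user = {u: frame(u) for u in ("a", "b", "c")}
        K = compute_pairwise_kappa_matrix(
            per_user, ClassifierSpec("logreg"), seed=0)
        off_diag = K.to_numpy()[~np.eye(3, dtype=bool)]
        np.testing.assert_allclose(off_diag, 1.0)

    def test_fitted_matrix_shape_and_diagonal(self, small_matrix):
        users = sorted(small_matrix["user"].unique())[:3]
        per_user = {u: small_matrix[small_matrix["user"] == u]
                    for u in users}
        K = compute_pairwise_kappa_matrix(
            per_user, ClassifierSpec("logreg"), seed=0)
        assert K.shape == (3, 3)
        assert K.isna().to_numpy().trace() == 3
        assert K.notna().sum().sum() == 6

    def test_asymmetric_class_coverage_gives_asymmetric_kappa(self):
        # user a covers {A, B}; user b covers only A-like rows labelled
        # half A half B -> transfer quality differs by direction
        rng = np.random.default_rng(1)
        def frame(user, labels, centres):
            rows = []
            for i, (lab, c) in enumerate(zip(labels, centres)):
                for _ in range(20):
                    rows.append({"user": user, "trial": f"{user}{i}",
                                 "label": lab,
                                 "f0": rng.normal(c, 0.1),
                                 "f1": rng.normal(-c, 0.1)})
            return pd.DataFrame(rows)
        per_user = {
            "a": frame("a", ["A", "B"], [0.0, 3.0]),
            "b": frame("b", ["A", "B"], [0.0, 0.1]),   # nearly collapsed
            "c": frame("c", ["A", "B"], [0.0, 3.0]),
        }
        K = compute_pairwise_kappa_matrix(
            per_user, ClassifierSpec("logreg"), seed=0)
        assert K.loc["a", "b"] != pytest.approx(K.loc["b", "a"], abs=1e-3)


class TestKappaWeights:
    def _K(self, values):
        users = list(values)
        K = pd.DataFrame(np.nan, index=users, columns=users, dtype=float)
        for u, row in values.items():
            for v, val in row.items():
                K.loc[u, v] = val
        return K

    def test_normalisation(self):
        K = self._K({"a": {"b": 0.5, "c": 0.5},
                     "b": {"a": 0.25, "c": 0.25},
                     "c": {"a": 0.0, "b": 0.0}})
        w = compute_kappa_weights(K, "c", ["a", "b"])
        np.testing.assert_allclose(w, [2 / 3, 1 / 3])

    def test_negative_means_clipped(self):
        K = self._K({"a": {"b": -0.2, "c": -0.2},
                     "b": {"a": 0.4, "c": 0.4},
                     "c": {"a": 0.0, "b": 0.0}})
        w = compute_kappa_weights(K, "c", ["a", "b"])
        np.testing.assert_allclose(w, [0.0, 1.0])

    def test_test_user_excluded_from_average(self):
        # member a: kappa 1.0 on the test user t but 0 on fellow member b
        K = self._K({"a": {"b": 0.0, "t": 1.0},
                     "b": {"a": 0.5, "t": 0.0}})
        w = compute_kappa_weights(K, "t", ["a", "b"])
        np.testing.assert_allclose(w, [0.0, 1.0])

    def test_all_equal_reduces_to_uniform(self):
        K = self._K({"a": {"b": 0.3, "c": 0.3},
                     "b": {"a": 0.3, "c": 0.3},
                     "c": {"a": 0.3, "b": 0.3}})
        w = compute_kappa_weights(K, "d", ["a", "b", "c"])
        np.testing.assert_allclose(w, [1 / 3, 1 / 3, 1 / 3])

    def test_all_zero_falls_back_to_uniform(self):
        K = self._K({"a": {"b": -1.0, "c": -1.0},
                     "b": {"a": -1.0, "c": -1.0},
                     "c": {"a": -1.0, "b": -1.0}})
        w = compute_kappa_weights(K, "d", ["a", "b", "c"])
        np.testing.assert_allclose(w, [1 / 3, 1 / 3, 1 / 3])


class TestBaselineFeatures:
    def test_one_vector_per_present_baseline_label(self, small_matrix):
        sub = small_matrix[small_matrix["user"] == "user00"]
        base = compute_baseline_features(sub, rng=0)
        assert base.shape == (2, 56)      # standing and sitting present

    def test_missing_label_yields_fewer_vectors(self, small_matrix):
        sub = small_matrix[(small_matrix["user"] == "user00")
                           & (small_matrix["label"] != "standing")]
        base = compute_baseline_features(sub, rng=0)
        assert base.shape == (1, 56)

    def test_no_baseline_rows_empty(self, small_matrix):
        sub = small_matrix[small_matrix["label"] == "walking"]
        base = compute_baseline_features(sub, rng=0)
        assert base.shape[0] == 0

    def test_deterministic_given_seed(self, small_matrix):
        sub = small_matrix[small_matrix["user"] == "user01"]
        a = compute_baseline_features(sub, rng=123)
        b = compute_baseline_features(sub, rng=123)
        np.testing.assert_array_equal(a, b)


class TestBaselineWeights:
    def test_inverse_distance_arithmetic(self):
        member = {"a": np.array([[0.0, 0.0]]),
                  "b": np.array([[0.0, 0.0]])}
        test = np.array([[1.0, 0.0], [3.0, 0.0]])
        # mean distances: a -> 2, b -> 2 is degenerate; shift b
        member["b"] = np.array([[ -2.0, 0.0]])
        # d(a) = mean(1, 3) = 2; d(b) = mean(3, 5) = 4 -> raw (1/2, 1/4)
        w = compute_baseline_weights(member, test)
        np.testing.assert_allclose(w, [2 / 3, 1 / 3], atol=1e-6)

    def test_identical_baseline_dominates(self):
        member = {"a": np.array([[1.0, 1.0]]),
                  "b": np.array([[5.0, 5.0]])}
        test = np.array([[1.0, 1.0]])
        w = compute_baseline_weights(member, test)
        assert w[0] > 0.999

    def test_empty_member_gets_mean_raw_weight(self):
        member = {"a": np.array([[0.0]]), "b": np.empty((0, 1)),
                  "c": np.array([[2.0]])}
        test = np.array([[1.0]])
        w = compute_baseline_weights(member, test)
        # raw: a = 1, c = 1, b = mean = 1 -> uniform
        np.testing.assert_allclose(w, [1 / 3, 1 / 3, 1 / 3], atol=1e-6)

    def test_empty_test_baselines_uniform(self):
        member = {"a": np.array([[0.0]]), "b": np.array([[9.0]])}
        w = compute_baseline_weights(member, np.empty((0, 1)))
        np.testing.assert_allclose(w, [0.5, 0.5])


class TestSchemeReduction:
    def test_equal_weights_reproduce_unweighted_predictions(self,
                                                            small_matrix):
        per_user = {u: small_matrix[small_matrix["user"] == u]
                    for u in sorted(small_matrix["user"].unique())[:3]}
        cols = feature_columns(small_matrix)
        X = small_matrix[cols].to_numpy()[:50]
        uniform = fit_epsm(per_user, ClassifierSpec("logreg"), "uniform",
                           seed=0)
        base = predict_unknown_user(uniform, "t", X)
        for scheme in ("kappa", "baseline"):
            ens = fit_epsm(per_user, ClassifierSpec("logreg"), scheme,
                           seed=0)
            ens.weight_table["t"] = np.full(3, 1 / 3)
            np.testing.assert_array_equal(
                predict_unknown_user(ens, "t", X), base)
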