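"""Personalisation-generalisation approaches.

Three families of models map windows to activities:

* **PIM** (person-independent model): one classifier trained on pooled data
  from all training users.
* **PSM** (person-specific model): a classifier trained on a single user's
  data only.
* **EPSM** (ensemble of PSMs): keeps a PSM per known user.  For a known
  user it simply applies that user's PSM; for an unknown user it averages
  the members' per-activity confidence scores and predicts the activity
  with the maximum (weighted) mean score.  A member whose training data
  lacked some activity contributes an exact zero score for it.

Two weighting schemes refine the ensemble's average for unknown users:

* **WEPSM** weights each member by its mean Cohen's kappa measured on the
  other training users (negative means are clipped to zero);
* **WEPSMbf** weights each member by the inverse mean Euclidean distance
  between its user's and the test user's *baseline features* — feature
  vectors of one randomly chosen standing and sitting window, a cheap
  posture fingerprint obtainable from a new user without labelled motion
  data.

All classifiers sit behind a probabilistic-score contract: ``fit`` on
labelled feature rows, ``predict_scores`` returning per-row non-negative
scores over the model's own class inventory, summing to 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .errors import EpsmError
from .features import feature_columns
from .metrics import cohen_kappa

log = logging.getLogger(__name__)

#: labels treated as posture baselines for WEPSMbf weighting
DEFAULT_BASELINE_LABELS = ("standing", "sitting")

_EPS_DISTANCE = 1e-8    # regulariser for inverse-distance weights

#: published hyperparameter settings per algorithm
DEFAULT_HYPERPARAMETERS: dict[str, dict] = {
    "logreg": {"C": 0.98},
    "knn": {"n_neighbors": 2, "weights": "distance"},
    "svm": {"gamma": 0.001, "C": 316.0},
    "gbt": {"learning_rate": 0.02, "n_estimators": 750},
}


@dataclass(frozen=True)
class ClassifierSpec:
    """A learning algorithm plus hyperparameters.

    Defaults are the reference configuration: ridge-penalised logistic
    regression with C = 0.98; kNN with k = 2 and distance-weighted voting;
    an RBF SVM with gamma = 0.001 and C = 316; gradient boosted trees with
    learning rate 0.02 and 750 trees.
    """

    algorithm: str = "logreg"
    hyperparameters: Mapping | None = None

    def resolved_hyperparameters(self) -> dict:
        if self.algorithm not in DEFAULT_HYPERPARAMETERS:
            raise EpsmError(
                f"unknown algorithm {self.algorithm!r}; expected one of "
                f"{sorted(DEFAULT_HYPERPARAMETERS)}")
        params = dict(DEFAULT_HYPERPARAMETERS[self.algorithm])
        if self.hyperparameters:
            params.update(self.hyperparameters)
        return params


def _make_estimator(spec: ClassifierSpec, seed: int | None):
    params = spec.resolved_hyperparameters()
    if spec.algorithm == "logreg":
        return LogisticRegression(max_iter=2000, **params)
    if spec.algorithm == "knn":
        return KNeighborsClassifier(**params)
    if spec.algorithm == "svm":
        return SVC(kernel="rbf", probability=True, random_state=seed,
                   **params)
    if spec.algorithm == "gbt":
        return GradientBoostingClassifier(random_state=seed, **params)
    raise EpsmError(f"unknown algorithm {spec.algorithm!r}")


class ProbabilisticClassifier:
    """Score-contract wrapper around a scikit-learn estimator.

    The class inventory is the sorted distinct training labels; score rows
    are non-negative and sum to 1.
    """

    def __init__(self, spec: ClassifierSpec, seed: int | None = None):
        self.spec = spec
        self._estimator = _make_estimator(spec, seed)
        self.classes_: np.ndarray | None = None

    def fit(self, features: np.ndarray, labels: Sequence) -> "ProbabilisticClassifier":
        labels = np.asarray(labels, dtype=object)
        if len(labels) == 0:
            raise EpsmError("cannot fit a classifier on zero rows")
        self._estimator.fit(np.asarray(features, dtype=float), labels)
        self.classes_ = np.asarray(self._estimator.classes_, dtype=object)
        return self

    def predict_scores(self, features: np.ndarray) -> np.ndarray:
        if self.classes_ is None:
            raise EpsmError("classifier used before fitting")
        scores = self._estimator.predict_proba(
            np.asarray(features, dtype=float))
        return np.asarray(scores, dtype=float)

    def predict(self, features: np.ndarray) -> np.ndarray:
        """Argmax labels; ties resolve to the first class in sorted order."""
        scores = self.predict_scores(features)
        return self.classes_[np.argmax(scores, axis=1)]


def _split_xy(matrix: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    cols = feature_columns(matrix)
    return (matrix[cols].to_numpy(dtype=float),
            matrix["label"].to_numpy(dtype=object))


def fit_pim(train: pd.DataFrame, spec: ClassifierSpec,
            seed: int | None = None) -> ProbabilisticClassifier:
    """Fit one person-independent model on all training users pooled."""
    X, y = _split_xy(train)
    if len(np.unique(y)) < 2:
        raise EpsmError(
            "PIM training data must contain at least two classes")
    return ProbabilisticClassifier(spec, seed).fit(X, y)


def fit_psm(train: pd.DataFrame, spec: ClassifierSpec,
            seed: int | None = None) -> ProbabilisticClassifier:
    """Fit one person-specific model on a single user's data."""
    X, y = _split_xy(train)
    return ProbabilisticClassifier(spec, seed).fit(X, y)


@dataclass
class EnsembleOfPSMs:
    """Per-user fitted PSMs plus the global class inventory and weights.

    ``weight_table`` maps a test-user id to the member weights (in
    ``member_order``) used when that user is unknown; missing entries fall
    back to uniform weights.
    """

    members: dict
    global_classes: np.ndarray
    scheme: str = "uniform"                  # uniform | kappa | baseline
    weight_table: dict = field(default_factory=dict)

    @property
    def member_order(self) -> list:
        return list(self.members)

    def weights_for(self, test_user) -> np.ndarray:
        n = len(self.members)
        w = self.weight_table.get(test_user)
        if w is None:
            return np.full(n, 1.0 / n)
        w = np.asarray(w, dtype=float)
        if w.sum() <= 0:
            log.warning(
                "all member weights zero for test user %s; falling back "
                "to uniform", test_user)
            return np.full(n, 1.0 / n)
        return w / w.sum()


def fit_epsm(
    per_user_train: Mapping[object, pd.DataFrame],
    spec: ClassifierSpec,
    scheme: str = "uniform",
    seed: int | None = None,
    baseline_labels: Sequence[str] = DEFAULT_BASELINE_LABELS,
) -> EnsembleOfPSMs:
    """Fit one PSM per user and assemble them into an ensemble.

    ``scheme`` selects how unknown-user weights are derived: ``uniform``
    (EPSM), ``kappa`` (WEPSM, via :func:`compute_pairwise_kappa_matrix` and
    :func:`compute_kappa_weights`) or ``baseline`` (WEPSMbf; weights are
    computed lazily per test user with :func:`compute_baseline_weights`).
    Users with zero feature rows are skipped with a warning.
    """
    if scheme not in ("uniform", "kappa", "baseline"):
        raise EpsmError(f"unknown weighting scheme {scheme!r}")
    members: dict = {}
    kept: dict = {}
    for user, matrix in per_user_train.items():
        if matrix.empty:
            log.warning("user %s has no feature rows; skipping member", user)
            continue
        members[user] = fit_psm(matrix, spec, seed)
        kept[user] = matrix
    if not members:
        raise EpsmError("no users with data; cannot fit an ensemble")
    global_classes = np.asarray(sorted({
        c for m in members.values() for c in m.classes_}), dtype=object)
    ensemble = EnsembleOfPSMs(
        members=members, global_classes=global_classes, scheme=scheme)
    if scheme == "kappa":
        if len(kept) < 3:
            log.warning(
                "kappa weighting needs >= 3 members; using uniform weights")
        else:
            K = compute_pairwise_kappa_matrix(kept, spec, members=members)
            ensemble._kappa_matrix = K  # cached for per-test-user weights
    if scheme == "baseline":
        rng = np.random.default_rng(seed)
        ensemble._member_baselines = {
            user: compute_baseline_features(matrix, baseline_labels, rng)
            for user, matrix in kept.items()}
    return ensemble


def align_scores(
    scores: np.ndarray,
    member_classes: np.ndarray,
    global_classes: np.ndarray,
) -> np.ndarray:
    """Embed a member's score rows into the global class inventory.

    Classes absent from the member's inventory receive exactly zero — a
    user who never performed an activity is assumed never to perform it.
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    positions = {c: i for i, c in enumerate(global_classes)}
    out = np.zeros((scores.shape[0], len(global_classes)))
    for j, cls in enumerate(member_classes):
        if cls not in positions:
            raise EpsmError(
                f"member class {cls!r} missing from the global inventory")
        out[:, positions[cls]] = scores[:, j]
    return out


def predict_known_user(
    ensemble: EnsembleOfPSMs, user, features: np.ndarray
) -> np.ndarray:
    """For a known user the ensemble is exactly that user's PSM."""
    if user not in ensemble.members:
        raise EpsmError(
            f"user {user!r} is not an ensemble member; use "
            "predict_unknown_user")
    return ensemble.members[user].predict(features)


def predict_unknown_user(
    ensemble: EnsembleOfPSMs,
    test_user,
    features: np.ndarray,
    return_scores: bool = False,
):
    """Weighted-mean-score prediction for a user without a PSM.

    Aggregated score rows are the convex combination of the members'
    aligned score rows and therefore sum to 1; the predicted label is the
    argmax, with ties broken by the lowest index in the sorted global
    inventory.
    """
    weights = ensemble.weights_for(test_user)
    agg = np.zeros((len(features), len(ensemble.global_classes)))
    for w, (user, member) in zip(weights, ensemble.members.items()):
        if w == 0:
            continue
        aligned = align_scores(
            member.predict_scores(features), member.classes_,
            ensemble.global_classes)
        agg += w * aligned
    labels = ensemble.global_classes[np.argmax(agg, axis=1)]
    return (labels, agg) if return_scores else labels


def prepare_weights(
    ensemble: EnsembleOfPSMs,
    test_user,
    test_data: pd.DataFrame | None = None,
    baseline_labels: Sequence[str] = DEFAULT_BASELINE_LABELS,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Fill the ensemble's weight-table row for one unknown test user.

    Uniform scheme: 1/n each.  Kappa scheme: derived from the cached
    pairwise kappa matrix.  Baseline scheme: requires ``test_data`` (the
    test user's standardised feature rows) to draw their baseline windows.
    """
    n = len(ensemble.members)
    if ensemble.scheme == "uniform":
        w = np.full(n, 1.0 / n)
    elif ensemble.scheme == "kappa":
        K = getattr(ensemble, "_kappa_matrix", None)
        w = (np.full(n, 1.0 / n) if K is None else
             compute_kappa_weights(K, test_user, ensemble.member_order))
    elif ensemble.scheme == "baseline":
        if test_data is None:
            raise EpsmError(
                "baseline weighting needs the test user's feature rows")
        test_baselines = compute_baseline_features(
            test_data, baseline_labels, rng)
        if len(test_baselines) == 0:
            log.warning(
                "test user %s has no baseline-label rows; using uniform "
                "baseline weights", test_user)
        w = compute_baseline_weights(
            ensemble._member_baselines, test_baselines)
    else:   # pragma: no cover - scheme validated at fit time
        raise EpsmError(f"unknown weighting scheme {ensemble.scheme!r}")
    ensemble.weight_table[test_user] = w
    return w


def compute_pairwise_kappa_matrix(
    per_user_data: Mapping[object, pd.DataFrame],
    spec: ClassifierSpec,
    seed: int | None = None,
    members: Mapping[object, ProbabilisticClassifier] | None = None,
) -> pd.DataFrame:
    """K[u, v]: Cohen's kappa of user u's PSM evaluated on user v's rows.

    The diagonal is left NaN (a PSM's agreement with its own training data
    is not a transfer measure).  K is not symmetric in general.  Pre-fitted
    members may be supplied to avoid refitting.
    """
    users = list(per_user_data)
    if len(users) < 3:
        raise EpsmError(
            "pairwise kappa weights need at least three users")
    if members is None:
        members = {u: fit_psm(per_user_data[u], spec, seed) for u in users}
    K = pd.DataFrame(np.nan, index=users, columns=users, dtype=float)
    for v in users:
        X_v, y_v = _split_xy(per_user_data[v])
        for u in users:
            if u == v:
                continue
            K.loc[u, v] = cohen_kappa(y_v, members[u].predict(X_v)).kappa
    return K


def compute_kappa_weights(
    K: pd.DataFrame, test_user, members: Sequence
) -> np.ndarray:
    """Normalised member weights from the pairwise kappa matrix.

    Each member's raw weight is its mean kappa over the *other* members —
    excluding itself and the test user.  Negative means are clipped to zero
    (an anti-correlated PSM should not vote); an all-zero vector falls back
    to uniform.
    """
    members = list(members)
    raw = np.zeros(len(members))
    for i, u in enumerate(members):
        others = [v for v in members if v != u and v != test_user]
        if len(others) < 1:
            log.warning(
                "fewer than two members besides the test user; using "
                "uniform kappa weights")
            return np.full(len(members), 1.0 / len(members))
        raw[i] = float(np.mean([K.loc[u, v] for v in others]))
    raw = np.clip(raw, 0.0, None)
    if raw.sum() <= 0:
        return np.full(len(members), 1.0 / len(members))
    return raw / raw.sum()


def compute_baseline_features(
    user_data: pd.DataFrame,
    baseline_labels: Sequence[str] = DEFAULT_BASELINE_LABELS,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """One uniformly random feature row per baseline label present.

    Returns an array of shape (n_baselines, n_features) with 0-2 rows;
    deterministic given the generator state.
    """
    rng = np.random.default_rng(rng) if not isinstance(
        rng, np.random.Generator) else rng
    cols = feature_columns(user_data)
    rows = []
    for lab in baseline_labels:
        sub = user_data[user_data["label"] == lab]
        if sub.empty:
            continue
        pick = int(rng.integers(len(sub)))
        rows.append(sub.iloc[pick][cols].to_numpy(dtype=float))
    if not rows:
        return np.empty((0, len(cols)))
    return np.vstack(rows)


def compute_baseline_weights(
    member_baselines: Mapping[object, np.ndarray],
    test_baselines: np.ndarray,
) -> np.ndarray:
    """Inverse-mean-distance member weights from baseline features.

    For each member, the mean Euclidean distance between all (member
    vector, test vector) pairs is inverted (with a small epsilon) so that
    posturally closer users vote more.  Members without baselines — or all
    members, when the test user has none — receive the mean raw weight of
    the others (uniform if there are none).
    """
    users = list(member_baselines)
    raw = np.full(len(users), np.nan)
    if len(test_baselines):
        for i, u in enumerate(users):
            mb = member_baselines[u]
            if len(mb) == 0:
                continue
            d = np.linalg.norm(
                mb[:, None, :] - test_baselines[None, :, :], axis=2)
            raw[i] = 1.0 / (float(d.mean()) + _EPS_DISTANCE)
    known = np.isfinite(raw)
    if not known.any():
        return np.full(len(users), 1.0 / len(users))
    raw[~known] = raw[known].mean()
    return raw / raw.sum()
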