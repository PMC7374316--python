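"""Cross-validation protocols, approach evaluation, ranking and summaries.

Two performance notions are estimated:

* **Subject-dependent** — accuracy for users represented in the training
  data, estimated by *leave-trials-out* k-fold cross-validation: folds are
  formed from whole trials so that overlapping sliding windows derived from
  the same raw signal never straddle a train/test split.  k equals the
  number of users n in the dataset, both for the pooled PIM CV and for each
  user's own PSM CV.
* **Subject-independent** — accuracy for unseen users, estimated by
  leave-m-users-out cross-validation with m = 1 for PIM and the ensembles
  (train on n-1 users, test on the held-out one) and m = n-1 for PSM
  (train on one user, test on the remaining n-1, averaged per test user).

Feature standardisation is refit inside every training split.  Results are
reported per held-out user so that downstream mixed-model analyses can
treat users as the unit of observation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from .errors import EpsmError, ProtocolError
from .features import Standardizer, feature_columns
from .io import EvaluationResult
from .metrics import KappaStat, classification_metrics, cohen_kappa
from .models import (
    ClassifierSpec,
    fit_epsm,
    fit_pim,
    fit_psm,
    predict_unknown_user,
    prepare_weights,
)

log = logging.getLogger(__name__)

__all__ = [
    "SplitPlan", "KappaStat", "cohen_kappa", "classification_metrics",
    "make_leave_trials_out_folds", "make_leave_users_out_folds",
    "evaluate_approach", "rank_methods", "summarise", "paired_t",
]


@dataclass
class SplitPlan:
    """Cross-validation folds over the rows of one feature matrix.

    Each fold is a (train positional-index array, test positional-index
    array) pair; test sets are pairwise disjoint and cover all rows, and no
    grouping unit (trial or user) appears on both sides of one fold.
    """

    folds: list
    grouping: str           # "trial" | "user"
    k: int


def make_leave_trials_out_folds(
    matrix: pd.DataFrame, k: int, seed: int | None = None
) -> SplitPlan:
    """k folds with whole trials as the grouping unit.

    Within every (user, activity) stratum the trial ids are shuffled
    (seeded) and dealt round-robin to the k folds, keeping every class
    represented on the training side.  A stratum with fewer than two trials
    cannot be split and raises a protocol error naming it.
    """
    if k < 2:
        raise ProtocolError(f"leave-trials-out needs k >= 2, got {k}")
    rng = np.random.default_rng(seed)
    trial_fold: dict = {}
    for (user, label), sub in matrix.groupby(["user", "label"], sort=True):
        trials = sub["trial"].unique()      # first-appearance order
        if len(trials) < 2:
            raise ProtocolError(
                f"user {user!r}, activity {label!r} has only "
                f"{len(trials)} trial(s); leave-trials-out needs >= 2")
        trials = trials[rng.permutation(len(trials))]
        for i, t in enumerate(trials):
            trial_fold[t] = i % k
    assignment = matrix["trial"].map(trial_fold).to_numpy()
    folds = []
    for fold in range(k):
        test = np.flatnonzero(assignment == fold)
        train = np.flatnonzero(assignment != fold)
        if len(test) == 0:
            continue        # more folds than trials in every stratum
        folds.append((train, test))
    return SplitPlan(folds=folds, grouping="trial", k=k)


def make_leave_users_out_folds(matrix: pd.DataFrame, m: int) -> SplitPlan:
    """Leave-m-users-out folds; only m = 1 and m = n - 1 are meaningful.

    m = 1: n folds, each testing on one held-out user.  m = n - 1: n folds,
    each training on exactly one user and testing on all the others.
    """
    users = sorted(matrix["user"].unique())
    n = len(users)
    if n < 2:
        raise ProtocolError("leave-users-out needs at least two users")
    if m not in (1, n - 1):
        raise ProtocolError(
            f"unsupported protocol: m={m} with n={n} users "
            "(only m=1 and m=n-1 are defined)")
    user_col = matrix["user"].to_numpy()
    folds = []
    for u in users:
        mask = user_col == u
        if m == 1:
            folds.append((np.flatnonzero(~mask), np.flatnonzero(mask)))
        else:
            folds.append((np.flatnonzero(mask), np.flatnonzero(~mask)))
    return SplitPlan(folds=folds, grouping="user", k=n)


def _metrics_record(dataset, sensor, user, algorithm, approach,
                    performance_type, y_true, y_pred) -> EvaluationResult:
    m = classification_metrics(y_true, y_pred)
    return EvaluationResult(
        dataset=dataset, sensor=sensor, user=str(user),
        algorithm=algorithm, approach=approach,
        performance_type=performance_type,
        kappa=cohen_kappa(y_true, y_pred).kappa,
        accuracy=m["accuracy"], error_rate=m["error_rate"],
        weighted_f=m["weighted_f"])


def _cv_predict(matrix: pd.DataFrame, plan: SplitPlan,
                spec: ClassifierSpec, seed) -> np.ndarray:
    """Out-of-fold predictions for every row, with per-fold refits of the
    standardiser and classifier."""
    cols = feature_columns(matrix)
    preds = np.empty(len(matrix), dtype=object)
    for train_idx, test_idx in plan.folds:
        train = matrix.iloc[train_idx]
        test = matrix.iloc[test_idx]
        scaler = Standardizer().fit(train)
        model = fit_psm(scaler.transform(train), spec, seed)
        preds[test_idx] = model.predict(
            scaler.transform(test)[cols].to_numpy(dtype=float))
    if any(p is None for p in preds):
        raise EpsmError("cross-validation left rows without predictions")
    return preds


def _subject_dependent_pim(matrix, spec, dataset, sensor, algorithm,
                           seed) -> list[EvaluationResult]:
    users = sorted(matrix["user"].unique())
    plan = make_leave_trials_out_folds(matrix, k=len(users), seed=seed)
    preds = _cv_predict(matrix, plan, spec, seed)
    y = matrix["label"].to_numpy(dtype=object)
    user_col = matrix["user"].to_numpy()
    return [
        _metrics_record(dataset, sensor, u, algorithm, "PIM",
                        "subject_dependent",
                        y[user_col == u], preds[user_col == u])
        for u in users
    ]


def _subject_dependent_psm(matrix, spec, dataset, sensor, algorithm,
                           seed, approach="PSM") -> list[EvaluationResult]:
    users = sorted(matrix["user"].unique())
    k = len(users)      # k = n also for the per-user CVs
    records = []
    for u in users:
        sub = matrix[matrix["user"] == u].reset_index(drop=True)
        plan = make_leave_trials_out_folds(sub, k=k, seed=seed)
        preds = _cv_predict(sub, plan, spec, seed)
        records.append(_metrics_record(
            dataset, sensor, u, algorithm, approach, "subject_dependent",
            sub["label"].to_numpy(dtype=object), preds))
    return records


def _subject_independent_pim(matrix, spec, dataset, sensor, algorithm,
                             seed) -> list[EvaluationResult]:
    plan = make_leave_users_out_folds(matrix, m=1)
    cols = feature_columns(matrix)
    records = []
    for train_idx, test_idx in plan.folds:
        train = matrix.iloc[train_idx]
        test = matrix.iloc[test_idx]
        scaler = Standardizer().fit(train)
        model = fit_pim(scaler.transform(train), spec, seed)
        preds = model.predict(
            scaler.transform(test)[cols].to_numpy(dtype=float))
        user = test["user"].iloc[0]
        records.append(_metrics_record(
            dataset, sensor, user, algorithm, "PIM", "subject_independent",
            test["label"].to_numpy(dtype=object), preds))
    return records


def _subject_independent_psm(
    matrix, spec, dataset, sensor, algorithm, seed,
    return_pairs: bool = False,
):
    """Train on one user, test on each other user; report per test user
    the mean metric over its n-1 single-user-trained models."""
    users = sorted(matrix["user"].unique())
    cols = feature_columns(matrix)
    per_user = {u: matrix[matrix["user"] == u] for u in users}
    pair_rows = []      # (train_user, test_user, metrics)
    for u in users:
        scaler = Standardizer().fit(per_user[u])
        model = fit_psm(scaler.transform(per_user[u]), spec, seed)
        for v in users:
            if v == u:
                continue
            test = scaler.transform(per_user[v])
            preds = model.predict(test[cols].to_numpy(dtype=float))
            y = per_user[v]["label"].to_numpy(dtype=object)
            m = classification_metrics(y, preds)
            pair_rows.append({
                "train_user": u, "test_user": v,
                "kappa": cohen_kappa(y, preds).kappa, **m})
    pairs = pd.DataFrame(pair_rows)
    records = []
    for v in users:
        sub = pairs[pairs["test_user"] == v]
        acc = float(sub["accuracy"].mean())
        records.append(EvaluationResult(
            dataset=dataset, sensor=sensor, user=str(v),
            algorithm=algorithm, approach="PSM",
            performance_type="subject_independent",
            kappa=float(sub["kappa"].mean()), accuracy=acc,
            error_rate=1.0 - acc,
            weighted_f=float(sub["weighted_f"].mean())))
    return (records, pairs) if return_pairs else records


def _subject_independent_ensemble(
    matrix, spec, approach, dataset, sensor, algorithm, seed,
    baseline_labels,
) -> list[EvaluationResult]:
    scheme = {"EPSM": "uniform", "WEPSM": "kappa",
              "WEPSMbf": "baseline"}[approach]
    plan = make_leave_users_out_folds(matrix, m=1)
    cols = feature_columns(matrix)
    records = []
    for fold_i, (train_idx, test_idx) in enumerate(plan.folds):
        train = matrix.iloc[train_idx]
        test = matrix.iloc[test_idx]
        test_user = test["user"].iloc[0]
        scaler = Standardizer().fit(train)
        train_std = scaler.transform(train)
        test_std = scaler.transform(test)
        per_user = {u: train_std[train_std["user"] == u]
                    for u in sorted(train_std["user"].unique())}
        rng = np.random.default_rng(
            None if seed is None else seed + 7919 * fold_i)
        ensemble = fit_epsm(per_user, spec, scheme=scheme, seed=seed,
                            baseline_labels=baseline_labels)
        prepare_weights(ensemble, test_user, test_data=test_std,
                        baseline_labels=baseline_labels, rng=rng)
        preds = predict_unknown_user(
            ensemble, test_user, test_std[cols].to_numpy(dtype=float))
        records.append(_metrics_record(
            dataset, sensor, test_user, algorithm, approach,
            "subject_independent",
            test["label"].to_numpy(dtype=object), preds))
    return records


def evaluate_approach(
    matrix: pd.DataFrame,
    spec: ClassifierSpec,
    approach: str,
    performance_type: str,
    seed: int | None = None,
    dataset: str = "dataset",
    sensor: str = "other",
    baseline_labels: Sequence[str] = ("standing", "sitting"),
) -> list[EvaluationResult]:
    """Evaluate one personalisation-generalisation approach.

    Returns one :class:`~epsm.io.EvaluationResult` per user.  For the
    ensembles, subject-dependent evaluation dispatches each known user to
    their own PSM, so those rows equal the PSM rows with the approach name
    substituted.
    """
    algorithm = spec.algorithm
    if performance_type == "subject_dependent":
        if approach == "PIM":
            return _subject_dependent_pim(
                matrix, spec, dataset, sensor, algorithm, seed)
        if approach in ("PSM", "EPSM", "WEPSM", "WEPSMbf"):
            # known users are dispatched to their own PSM (ensembles are
            # identical to a PSM for subject-dependent predictions)
            return _subject_dependent_psm(
                matrix, spec, dataset, sensor, algorithm, seed,
                approach=approach)
    elif performance_type == "subject_independent":
        if approach == "PIM":
            return _subject_independent_pim(
                matrix, spec, dataset, sensor, algorithm, seed)
        if approach == "PSM":
            return _subject_independent_psm(
                matrix, spec, dataset, sensor, algorithm, seed)
        if approach in ("EPSM", "WEPSM", "WEPSMbf"):
            return _subject_independent_ensemble(
                matrix, spec, approach, dataset, sensor, algorithm, seed,
                baseline_labels)
    raise EpsmError(
        f"invalid approach/performance pair: {approach!r}, "
        f"{performance_type!r}")


def subject_independent_psm_pairs(
    matrix: pd.DataFrame, spec: ClassifierSpec, seed: int | None = None
) -> pd.DataFrame:
    """The full (train user, test user) transfer table behind the
    subject-independent PSM summary, including per-train-user medians."""
    _, pairs = _subject_independent_psm(
        matrix, spec, "dataset", "other", spec.algorithm, seed,
        return_pairs=True)
    return pairs


def rank_methods(results: Sequence[EvaluationResult]) -> pd.DataFrame:
    """Rank approaches by kappa within each (dataset, sensor, user,
    performance type); ties receive average ranks.  Users missing any
    approach present in their group's result set are excluded."""
    from .io import results_to_frame
    frame = results_to_frame(list(results))
    if frame.empty:
        return frame
    out = []
    for (ds, sen, ptype), sub in frame.groupby(
            ["dataset", "sensor", "performance_type"], sort=True):
        methods = set(sub["approach"].unique())
        for user, urows in sub.groupby("user", sort=True):
            if set(urows["approach"]) != methods:
                log.warning(
                    "user %s lacks some approaches; excluded from ranks",
                    user)
                continue
            urows = urows.copy()
            urows["rank"] = urows["kappa"].rank(
                ascending=False, method="average")
            out.append(urows)
    if not out:
        return pd.DataFrame()
    return pd.concat(out, ignore_index=True)[
        ["dataset", "sensor", "user", "algorithm", "approach",
         "performance_type", "kappa", "rank"]]


def summarise(results: Sequence[EvaluationResult]) -> pd.DataFrame:
    """Mean +/- standard error of each metric across users, per (dataset,
    sensor, algorithm, approach, performance type) cell.

    The SE uses the sample standard deviation (n - 1 denominator); a
    single-user cell reports SE = 0.
    """
    from .io import results_to_frame
    frame = results_to_frame(list(results))
    if frame.empty:
        return frame
    metrics = ["kappa", "accuracy", "error_rate", "weighted_f"]
    rows = []
    for key, sub in frame.groupby(
            ["dataset", "sensor", "algorithm", "approach",
             "performance_type"], sort=True):
        row = dict(zip(
            ["dataset", "sensor", "algorithm", "approach",
             "performance_type"], key))
        n = len(sub)
        row["n_users"] = n
        for m in metrics:
            row[f"{m}_mean"] = float(sub[m].mean())
            row[f"{m}_se"] = (
                float(sub[m].std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0)
        rows.append(row)
    return pd.DataFrame(rows)


def paired_t(x, y) -> dict[str, float]:
    """Paired t-test helper for comparing two approaches user-by-user.

    Returns the mean difference x - y, its 95% CI, t, degrees of freedom
    and the two-sided p-value.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    d = x - y
    n = len(d)
    res = sp_stats.ttest_rel(x, y)
    se = d.std(ddof=1) / np.sqrt(n)
    half = sp_stats.t.ppf(0.975, n - 1) * se
    return {
        "mean_diff": float(d.mean()),
        "ci_low": float(d.mean() - half),
        "ci_high": float(d.mean() + half),
        "t": float(res.statistic),
        "df": n - 1,
        "p": float(res.pvalue),
    }
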