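"""FOG-predisposition classifier on pre-walk sliding-window MI.

Each 0.2-s MI value from the walking-preparation interval [-20 s, -10 s]
becomes one single-feature sample labelled by its trial's FOG flag and
grouped by patient.  A support-vector classifier is trained on a grouped
80/20 split (whole patients on one side), with hyperparameters chosen by
grid search under group k-fold cross-validation (K = 10) so no patient's
samples ever straddle a train/validation or train/test boundary;
standardization statistics come from the training portion only.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import accuracy_score
from sklearn.model_selection import (
    GridSearchCV,
    GroupShuffleSplit,
    StratifiedGroupKFold,
)
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = ["FeatureSet", "EvalReport", "build_features", "train_eval",
           "PREWALK_INTERVAL"]

logger = logging.getLogger(__name__)

#: window-start interval of the walking-preparation feature samples, seconds
PREWALK_INTERVAL = (-20.0, -10.0)

#: hyperparameter grid: small, standard, reproducible
PARAM_GRID = [
    {"svc__kernel": ["rbf"], "svc__C": [0.1, 1.0, 10.0, 100.0],
     "svc__gamma": ["scale", 0.01, 0.1, 1.0]},
    {"svc__kernel": ["linear"], "svc__C": [0.1, 1.0, 10.0, 100.0]},
]


@dataclass
class FeatureSet:
    """Per-sample feature table: value(s), FOG label, patient group,
    source trial/channel."""

    X: np.ndarray          # (n_samples, n_features)
    y: np.ndarray          # bool labels
    groups: np.ndarray     # patient ids
    source: pd.DataFrame   # per-sample (trial_id, channel, window_start_s)

    def __len__(self) -> int:
        return self.X.shape[0]


@dataclass
class EvalReport:
    accuracy: float                      # held-out accuracy, percent
    # chance level: accuracy of always predicting the training-portion
    # majority class on the held-out samples, percent
    majority_rate: float
    best_params: dict
    train_groups: tuple
    test_groups: tuple
    cv_fold_of_group: dict
    confusion_by_group: dict
    n_train: int
    n_test: int
    scaler_mean: np.ndarray = field(repr=False, default=None)
    scaler_scale: np.ndarray = field(repr=False, default=None)


def build_features(series_list, interval: tuple[float, float] = PREWALK_INTERVAL
                   ) -> FeatureSet:
    """One single-feature sample per 0.2-s MI value inside ``interval``
    (closed at both ends).  Series with no samples there are skipped with
    a warning; partial coverage contributes what it has."""
    lo, hi = interval
    xs, ys, gs, src = [], [], [], []
    for s in series_list:
        sel = (s.times >= lo - 1e-9) & (s.times <= hi + 1e-9)
        if not sel.any():
            logger.warning("series %s/%s has no windows in [%.1f, %.1f] s; skipped",
                           s.meta.get("trial_id"), s.meta.get("channel"), lo, hi)
            continue
        for t, v in zip(s.times[sel], s.values[sel]):
            xs.append([v])
            ys.append(bool(s.meta.get("fog", False)))
            gs.append(s.meta.get("patient_id"))
            src.append({"trial_id": s.meta.get("trial_id"),
                        "channel": s.meta.get("channel"),
                        "window_start_s": float(t)})
    if not xs:
        raise ValueError("no series contributed samples")
    return FeatureSet(X=np.asarray(xs, float), y=np.asarray(ys, bool),
                      groups=np.asarray(gs, object), source=pd.DataFrame(src))


def _assert_no_leakage(train_groups, test_groups, fold_of_group) -> None:
    """Structural leakage check, run on every evaluation."""
    overlap = set(train_groups) & set(test_groups)
    if overlap:
        raise AssertionError(f"patients in both train and test: {overlap}")
    # GroupKFold assigns each group to exactly one fold by construction;
    # fold_of_group being a mapping (one fold per group) certifies it.
    if len(fold_of_group) != len(set(train_groups)):
        raise AssertionError("CV folds do not partition the training patients")


def train_eval(features: FeatureSet, split: float = 0.8, k: int = 10,
               seed: int = 0) -> EvalReport:
    """Grouped 80/20 train/test split, grid-searched SVC under group
    k-fold CV, refit on the whole training portion, held-out accuracy.

    Deterministic given ``seed``.  Raises if the training portion has
    fewer patients than ``k`` (lower k) or only one class.
    """
    splitter = GroupShuffleSplit(n_splits=1, train_size=split, random_state=seed)
    train_idx, test_idx = next(splitter.split(features.X, features.y,
                                              features.groups))
    X_tr, y_tr, g_tr = (features.X[train_idx], features.y[train_idx],
                        features.groups[train_idx])
    X_te, y_te, g_te = (features.X[test_idx], features.y[test_idx],
                        features.groups[test_idx])
    n_groups = len(set(g_tr))
    if n_groups < k:
        raise ValueError(
            f"training portion has {n_groups} patients < k={k}; lower k")
    if len(set(y_tr.tolist())) < 2:
        raise ValueError("training portion contains a single class")
    # stratified grouping: whole patients stay in one fold (the anti-
    # leakage requirement) while labels are balanced across folds, so CV
    # training partitions do not degenerate to a single class
    cv = StratifiedGroupKFold(n_splits=k)
    fold_of_group: dict = {}
    for fold, (_, val) in enumerate(cv.split(X_tr, y_tr, g_tr)):
        for g in set(g_tr[val]):
            if g in fold_of_group and fold_of_group[g] != fold:
                raise AssertionError(f"patient {g} spans CV folds")
            fold_of_group[g] = fold
    _assert_no_leakage(g_tr, g_te, fold_of_group)
    pipe = Pipeline([("scale", StandardScaler()), ("svc", SVC())])
    search = GridSearchCV(pipe, PARAM_GRID, cv=cv, n_jobs=1,
                          scoring="accuracy", refit=True)
    search.fit(X_tr, y_tr, groups=g_tr)
    y_hat = search.predict(X_te)
    acc = accuracy_score(y_te, y_hat)
    confusion = {}
    for g in sorted(set(g_te)):
        m = g_te == g
        confusion[g] = {"n": int(m.sum()),
                        "correct": int((y_hat[m] == y_te[m]).sum()),
                        "label": bool(y_te[m][0])}
    majority_label = y_tr.mean() > 0.5       # tie predicts the negative class
    majority = float(np.mean(y_te == majority_label))
    scaler = search.best_estimator_.named_steps["scale"]
    return EvalReport(
        accuracy=100.0 * float(acc), best_params=dict(search.best_params_),
        train_groups=tuple(sorted(set(g_tr))), test_groups=tuple(sorted(set(g_te))),
        cv_fold_of_group=fold_of_group, confusion_by_group=confusion,
        n_train=len(train_idx), n_test=len(test_idx),
        majority_rate=100.0 * float(majority),
        scaler_mean=scaler.mean_.copy(), scaler_scale=scaler.scale_.copy(),
    )
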