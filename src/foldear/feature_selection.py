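"""SVM-driven recursive feature elimination with cross-validated sizing.

A linear-kernel SVM is refitted as features are removed one at a time, the
least important feature (smallest squared weight summed over the
one-vs-rest class weight vectors) going first; stratified 5-fold
cross-validated weighted F1 is then evaluated for every surviving feature
count along the elimination path, and the count with the best mean score
(smallest count on ties) is selected.  Permutation importance — the drop in
weighted F1 when one feature's column is shuffled — is reported separately.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.feature_selection import RFE
from sklearn.inspection import permutation_importance as _sk_permutation_importance
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.svm import LinearSVC


def _linear_svm(seed: int) -> LinearSVC:
    # RFE needs per-feature weights; the RBF classifier used downstream has none.
    return LinearSVC(C=1.0, max_iter=20_000, random_state=seed)


@dataclass
class SelectionResult:
    selected_names: list[str]
    cv_curve: dict[int, float]  # feature count -> mean CV weighted F1
    best_count: int
    ranking: list[str]  # elimination order, first eliminated first
    seed: int

    def __post_init__(self) -> None:
        best = min((c for c, s in self.cv_curve.items() if s == max(self.cv_curve.values())))
        if self.best_count != best:
            raise ValueError("best_count must be the argmax of cv_curve (ties -> smallest)")


@dataclass
class ImportanceReport:
    names: list[str]
    importances_mean: np.ndarray
    importances_std: np.ndarray
    repeats: int
    seed: int


def svm_rfecv(
    X: np.ndarray,
    y: np.ndarray,
    names: list[str] | None = None,
    folds: int = 5,
    seed: int = 0,
) -> SelectionResult:
    """Select the feature subset maximizing cross-validated weighted F1.

    ``X`` must already be standardized (linear-SVM weights are
    scale-sensitive).  The full elimination order is computed first by
    recursive elimination down to a single feature; the CV curve is then
    evaluated at every count 1..p over the same stratified folds.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    if X.shape[0] < folds:
        raise ValueError("need at least as many samples as folds")
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < folds:
        raise ValueError(
            "a class has fewer members than folds; stratified CV would leave a fold "
            "without it — use fewer folds or more data"
        )
    p = X.shape[1]
    if names is None:
        names = [f"f{i}" for i in range(p)]
    if len(names) != p:
        raise ValueError("names length must match feature count")

    # Elimination order: RFE down to one survivor gives ranking 1 (kept last)
    # through p (dropped first); importance = squared one-vs-rest weights summed.
    if p == 1:
        order = np.array([0])
    else:
        rfe = RFE(_linear_svm(seed), n_features_to_select=1, step=1)
        rfe.fit(X, y)
        order = np.argsort(-rfe.ranking_, kind="stable")  # first eliminated first
    kept_last_first = order[::-1]  # survivor first

    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    cv_curve: dict[int, float] = {}
    for count in range(1, p + 1):
        cols = np.sort(kept_last_first[:count])
        scores = cross_val_score(
            _linear_svm(seed), X[:, cols], y, cv=cv, scoring="f1_weighted"
        )
        cv_curve[count] = float(scores.mean())
    best = max(cv_curve.values())
    best_count = min(c for c, s in cv_curve.items() if s == best)
    selected = np.sort(kept_last_first[:best_count])
    return SelectionResult(
        selected_names=[names[i] for i in selected],
        cv_curve=cv_curve,
        best_count=best_count,
        ranking=[names[i] for i in order],
        seed=seed,
    )


def permutation_importance(
    model,
    X: np.ndarray,
    y: np.ndarray,
    names: list[str] | None = None,
    repeats: int = 10,
    seed: int = 0,
) -> ImportanceReport:
    """Mean/SD drop in weighted F1 over seeded column permutations."""
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    X = np.asarray(X, dtype=np.float64)
    if names is None:
        names = [f"f{i}" for i in range(X.shape[1])]
    res = _sk_permutation_importance(
        model, X, y, scoring="f1_weighted", n_repeats=repeats, random_state=seed
    )
    return ImportanceReport(
        names=list(names),
        importances_mean=res.importances_mean,
        importances_std=res.importances_std,
        repeats=repeats,
        seed=seed,
    )
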