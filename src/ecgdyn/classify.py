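"""Combined-feature discrimination: the 19-classifier LOOCV grid.

A fixed registry of 19 scikit-learn classifier configurations is
evaluated per binary comparison (and on the all-vs-all multi-class
task) under leave-one-out cross-validation, over per-lead feature sets
and the 15-lead ensemble.  Per comparison the best (lead set,
classifier) cell is selected by Accuracy, then F1, then AUC, then
lexicographic name.

Eighteen configurations carry explicitly pinned hyperparameters or
library defaults; the 19th slot (quadratic discriminant analysis) is
the package's own registry completion — treat its results as such,
not as a reference configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import FeatureMatrix
from .metrics import MetricReport, auc_binary, binary_metrics, \
    confusion_from_predictions, multiclass_metrics
from .screening import BinaryComparison, enumerate_comparisons

__all__ = ["ClassifierConfig", "CLASSIFIER_NAMES", "build_registry",
           "loocv_evaluate", "grid_run", "ALL_VS_ALL"]

ALL_VS_ALL = "Allvs.All"

CLASSIFIER_NAMES: tuple[str, ...] = (
    "AdaBoost", "BaggC", "DeTreeC", "ExTreeC", "GauNB", "GauPro",
    "GradBoost", "KNN", "LinDis", "LinSVC", "LogReg", "LogRegCV", "MLP",
    "OvsR", "QDA", "RF", "SGD", "SGDCMod", "SVC",
)


@dataclass
class ClassifierConfig:
    """One registry entry: a name, a factory, and its provenance note."""

    name: str
    factory: object = field(repr=False)
    note: str = ""
    seed: int = 0

    def build(self):
        return self.factory(self.seed)


def build_registry(seed: int = 0) -> list[ClassifierConfig]:
    """The 19 classifier configurations, reproducibly constructible.

    Non-default hyperparameters: DeTreeC max_depth=5; ExTreeC
    n_estimators=300; GauPro kernel 1.0*RBF(1.0); LogReg solver lbfgs;
    LogRegCV cv=3; MLP alpha=1, max_iter=1000; OvsR wraps a logistic
    regression with random_state=0; RF max_depth=5, n_estimators=300,
    max_features=1; SGD max_iter=100, tol=1e-3; SGDCMod uses the
    modified-Huber loss (which exposes probabilities); SVC gamma=auto.
    Everything else takes scikit-learn defaults.  A single seed governs
    every stochastic classifier.
    """
    from sklearn.discriminant_analysis import (
        LinearDiscriminantAnalysis, QuadraticDiscriminantAnalysis)
    from sklearn.ensemble import (
        AdaBoostClassifier, BaggingClassifier, ExtraTreesClassifier,
        GradientBoostingClassifier, RandomForestClassifier)
    from sklearn.gaussian_process import GaussianProcessClassifier
    from sklearn.gaussian_process.kernels import RBF
    from sklearn.linear_model import (
        LogisticRegression, LogisticRegressionCV, SGDClassifier)
    from sklearn.multiclass import OneVsRestClassifier
    from sklearn.naive_bayes import GaussianNB
    from sklearn.neighbors import KNeighborsClassifier
    from sklearn.neural_network import MLPClassifier
    from sklearn.svm import SVC, LinearSVC
    from sklearn.tree import DecisionTreeClassifier

    entries = [
        ClassifierConfig("AdaBoost", lambda s: AdaBoostClassifier(random_state=s),
                         "default parameters"),
        ClassifierConfig("BaggC", lambda s: BaggingClassifier(random_state=s),
                         "default parameters"),
        ClassifierConfig("DeTreeC",
                         lambda s: DecisionTreeClassifier(max_depth=5,
                                                          random_state=s),
                         "max_depth=5"),
        ClassifierConfig("ExTreeC",
                         lambda s: ExtraTreesClassifier(n_estimators=300,
                                                        random_state=s),
                         "n_estimators=300"),
        ClassifierConfig("GauNB", lambda s: GaussianNB(), "default parameters"),
        ClassifierConfig("GauPro",
                         lambda s: GaussianProcessClassifier(
                             kernel=1.0 * RBF(1.0), random_state=s),
                         "kernel 1.0*RBF(1.0)"),
        ClassifierConfig("GradBoost",
                         lambda s: GradientBoostingClassifier(random_state=s),
                         "default parameters"),
        ClassifierConfig("KNN", lambda s: KNeighborsClassifier(),
                         "default parameters"),
        ClassifierConfig("LinDis", lambda s: LinearDiscriminantAnalysis(),
                         "default parameters"),
        ClassifierConfig("LinSVC", lambda s: LinearSVC(random_state=s),
                         "default parameters"),
        ClassifierConfig("LogReg",
                         lambda s: LogisticRegression(solver="lbfgs",
                                                      random_state=s),
                         "solver=lbfgs"),
        ClassifierConfig("LogRegCV",
                         lambda s: LogisticRegressionCV(cv=3, random_state=s),
                         "cv=3"),
        ClassifierConfig("MLP",
                         lambda s: MLPClassifier(alpha=1, max_iter=1000,
                                                 random_state=s),
                         "alpha=1, max_iter=1000"),
        ClassifierConfig("OvsR",
                         lambda s: OneVsRestClassifier(
                             LogisticRegression(random_state=0)),
                         "one-vs-rest over logistic regression, random_state=0"),
        ClassifierConfig("QDA",
                         lambda s: QuadraticDiscriminantAnalysis(
                             solver="eigen", shrinkage="auto"),
                         "registry-completion slot; shrunk eigen solver so "
                         "per-class covariances stay defined on wide "
                         "matrices"),
        ClassifierConfig("RF",
                         lambda s: RandomForestClassifier(
                             max_depth=5, n_estimators=300, max_features=1,
                             random_state=s),
                         "max_depth=5, n_estimators=300, max_features=1"),
        ClassifierConfig("SGD",
                         lambda s: SGDClassifier(max_iter=100, tol=1e-3,
                                                 random_state=s),
                         "max_iter=100, tol=1e-3"),
        ClassifierConfig("SGDCMod",
                         lambda s: SGDClassifier(loss="modified_huber",
                                                 random_state=s),
                         "modified-Huber loss"),
        ClassifierConfig("SVC", lambda s: SVC(gamma="auto", random_state=s),
                         "gamma=auto"),
    ]
    for e in entries:
        e.seed = seed
    assert len(entries) == 19
    return entries


def _scores_for_auc(model, X: np.ndarray) -> tuple[np.ndarray | None, str]:
    """Continuous scores for AUC: decision function, else probability."""
    if hasattr(model, "decision_function"):
        try:
            return np.asarray(model.decision_function(X)), "decision_function"
        except Exception:
            pass
    if hasattr(model, "predict_proba"):
        try:
            return np.asarray(model.predict_proba(X)), "predict_proba"
        except Exception:
            pass
    return None, "hard_label"


def loocv_evaluate(
    matrix: FeatureMatrix,
    comparison: BinaryComparison | str,
    config: ClassifierConfig,
) -> MetricReport:
    """Leave-one-out evaluation of one classifier on one comparison.

    ``comparison`` is a :class:`BinaryComparison` (its first-named
    group is the positive class) or the string ``"Allvs.All"`` for the
    multi-class task.  One prediction is made per row; metrics are
    computed on the pooled held-out predictions.  AUC uses the
    classifier's decision function where available, probability second,
    hard labels last (recorded in ``auc_source``).
    """
    if isinstance(comparison, BinaryComparison):
        sub = matrix.select_groups([comparison.group_a, comparison.group_b])
        positive = comparison.group_a.value
    else:
        if comparison != ALL_VS_ALL:
            raise ValueError(f"unknown comparison {comparison!r}")
        sub = matrix
        positive = None
    X = sub.data.to_numpy(dtype=float)
    y = sub.groups.astype(str).to_numpy()
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError(f"comparison needs >= 2 classes, got {classes}")
    thin = classes[counts < 2]
    if len(thin):
        raise ValueError(
            f"class(es) {list(thin)} have a single record; LOOCV needs >= 2"
        )
    n = len(y)
    y_pred = np.empty(n, dtype=object)
    score_rows: list[np.ndarray | None] = []
    auc_source = "hard_label"
    sorted_classes = sorted(classes)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        model = config.build()
        model.fit(X[mask], y[mask])
        y_pred[i] = model.predict(X[i: i + 1])[0]
        s, src = _scores_for_auc(model, X[i: i + 1])
        if s is None:
            score_rows.append(None)
        else:
            auc_source = src
            score_rows.append(np.atleast_2d(s)[0])
    if positive is not None:
        rep = binary_metrics(confusion_from_predictions(y, y_pred, positive))
        if all(s is not None for s in score_rows):
            scores = np.vstack([np.atleast_1d(s) for s in score_rows])
            if scores.shape[1] == 1:          # decision function
                s_pos = scores[:, 0]
                # decision_function scores point toward classes_[1]
                if sorted_classes[1] != positive:
                    s_pos = -s_pos
            else:                              # probability matrix
                s_pos = scores[:, sorted_classes.index(positive)]
            rep.auc = auc_binary(y, s_pos, positive)
            rep.auc_source = auc_source
        else:
            rep.auc = auc_binary(y, (y_pred == positive).astype(float), positive)
            rep.auc_source = "hard_label"
        return rep
    # multi-class: probability matrices only are usable for OvR AUC
    proba_ok = (auc_source == "predict_proba"
                and all(s is not None and np.ndim(s) > 0
                        and len(np.atleast_1d(s)) == len(sorted_classes)
                        for s in score_rows))
    scores = (np.vstack([np.atleast_1d(s) for s in score_rows])
              if proba_ok else None)
    rep = multiclass_metrics(y, y_pred, scores=scores, classes=sorted_classes)
    rep.auc_source = auc_source if scores is not None else "none"
    return rep


def grid_run(
    matrix: FeatureMatrix,
    comparisons: list[BinaryComparison] | None = None,
    lead_sets: list[str] | None = None,
    classifiers: list[str] | None = None,
    seed: int = 0,
    include_all_vs_all: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Evaluate every (comparison x lead set x classifier) cell.

    ``lead_sets`` defaults to every lead present plus ``"ensemble"``
    (all leads concatenated — only offered when the matrix carries
    more than one lead).  Returns ``(reports, best)`` where ``best``
    has one row per comparison chosen by Accuracy, then F1, then AUC,
    then the (lead set, classifier) name pair.
    """
    if comparisons is None:
        from .screening import DEFAULT_GROUP_ORDER
        seen = set(matrix.groups.astype(str))
        comparisons = enumerate_comparisons(
            [g for g in DEFAULT_GROUP_ORDER if g.value in seen])
    leads = matrix.leads
    if lead_sets is None:
        lead_sets = list(leads) + (["ensemble"] if len(leads) > 1 else [])
    registry = {c.name: c for c in build_registry(seed)}
    if classifiers is None:
        classifiers = list(registry)
    unknown = set(classifiers) - set(registry)
    if unknown:
        raise KeyError(f"unknown classifier name(s): {sorted(unknown)}")
    tasks: list[BinaryComparison | str] = list(comparisons)
    if include_all_vs_all:
        tasks.append(ALL_VS_ALL)
    rows = []
    for task in tasks:
        label = task.label if isinstance(task, BinaryComparison) else task
        for lead_set in lead_sets:
            sub = matrix if lead_set == "ensemble" else matrix.select_lead(lead_set)
            for name in classifiers:
                try:
                    rep = loocv_evaluate(sub, task, registry[name])
                    row = rep.as_dict()
                    row["error"] = ""
                except (np.linalg.LinAlgError, ArithmeticError) as exc:
                    # a numerically infeasible cell must not void the grid
                    row = MetricReport().as_dict()
                    row["error"] = f"{type(exc).__name__}: {exc}"
                rows.append({
                    "comparison": label, "lead_set": lead_set,
                    "classifier": name, **row,
                })
    reports = pd.DataFrame(rows)
    best_rows = []
    for label, sub in reports.groupby("comparison", sort=False):
        ordered = sub.sort_values(
            by=["accuracy", "f1", "auc", "lead_set", "classifier"],
            ascending=[False, False, False, True, True],
            kind="mergesort", na_position="last",
        )
        best_rows.append(ordered.iloc[0].to_dict())
    best = pd.DataFrame(best_rows)
    return reports, best
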