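"""Six-classifier evaluation panel with a stratified 7:3 split.

The panel — SVM, MLP, random forest, AdaBoost, logistic regression and
Gaussian naive Bayes — is fitted per experimental group on one shared
stratified split and scored on the held-out set with accuracy,
sensitivity, specificity, PPV, NPV and AUC.  The positive class is poor
neurological function.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import GaussianNB
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

CLASSIFIER_KINDS = ("SVM", "MLP", "RF", "Ada", "LR", "NB")

#: Positive class is poor neurological function (label 1).
POSITIVE_LABEL = 1


@dataclass
class ClassifierSpec:
    kind: str
    seed: int = 0
    hyperparameters: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in CLASSIFIER_KINDS:
            raise ValueError(f"unknown classifier {self.kind!r}; panel: {CLASSIFIER_KINDS}")

    def build(self):
        hp = dict(self.hyperparameters)
        if self.kind == "SVM":
            return SVC(random_state=self.seed, **hp)
        if self.kind == "MLP":
            hp.setdefault("max_iter", 1000)
            return MLPClassifier(random_state=self.seed, **hp)
        if self.kind == "RF":
            return RandomForestClassifier(random_state=self.seed, **hp)
        if self.kind == "Ada":
            return AdaBoostClassifier(random_state=self.seed, **hp)
        if self.kind == "LR":
            hp.setdefault("max_iter", 5000)
            return LogisticRegression(random_state=self.seed, **hp)
        return GaussianNB(**hp)


def split_cohort(labels, ratio: float = 0.7, seed: int = 0):
    """Stratified train/test split with a fixed rounding convention.

    Per-class train counts: floor(n * ratio) for the class listed first
    (good, label 0), ceil for the other (poor, label 1) — so 45+45 at 0.7
    gives 31 good + 32 poor in training.  Returns (train_idx, test_idx)
    as integer positions; disjoint and exhaustive.
    """
    y = np.asarray(labels)
    rng = np.random.default_rng(seed)
    train, test = [], []
    for cls, rounder in ((0, np.floor), (1, np.ceil)):
        idx = np.nonzero(y == cls)[0]
        if len(idx) == 0:
            raise ValueError(f"class {cls} has no members")
        n_train = int(rounder(len(idx) * ratio))
        perm = rng.permutation(idx)
        train.extend(perm[:n_train])
        test.extend(perm[n_train:])
    return np.sort(np.array(train, dtype=int)), np.sort(np.array(test, dtype=int))


def fit_predict(spec: ClassifierSpec, X_train, y_train, X_test):
    """Fit on training rows only; return (predicted labels, positive-class scores).

    Scores are probabilities where the model exposes them, decision
    values otherwise; predictions use the model's default decision rule.
    """
    model = spec.build()
    Xtr = np.asarray(X_train, dtype=float)
    Xte = np.asarray(X_test, dtype=float)
    ytr = np.asarray(y_train)
    if len(np.unique(ytr)) < 2:
        raise ValueError("training set must contain both classes")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(Xtr, ytr)
        pred = model.predict(Xte)
        if hasattr(model, "predict_proba"):
            scores = model.predict_proba(Xte)[:, list(model.classes_).index(POSITIVE_LABEL)]
        else:
            scores = model.decision_function(Xte)
    return np.asarray(pred), np.asarray(scores, dtype=float)


def auc_score(y_true, scores) -> float:
    """Rank-statistic AUC (Mann-Whitney), ties counted half."""
    y = np.asarray(y_true)
    s = np.asarray(scores, dtype=float)
    pos = y == POSITIVE_LABEL
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes in the truth labels")
    ranks = rankdata(s)
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def compute_metrics(y_true, y_pred, scores=None) -> dict:
    """Confusion-matrix metrics (+AUC when scores given), positive = poor."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("length mismatch between truth and predictions")
    if len(np.unique(y_true)) < 2:
        raise ValueError("single-class truth; sensitivity/specificity undefined")
    pos = y_true == POSITIVE_LABEL
    tp = int(np.sum(pos & (y_pred == POSITIVE_LABEL)))
    fn = int(np.sum(pos & (y_pred != POSITIVE_LABEL)))
    tn = int(np.sum(~pos & (y_pred != POSITIVE_LABEL)))
    fp = int(np.sum(~pos & (y_pred == POSITIVE_LABEL)))
    out = {
        "TP": tp, "FP": fp, "TN": tn, "FN": fn,
        "accuracy": (tp + tn) / (tp + tn + fp + fn),
        "sensitivity": tp / (tp + fn),
        "specificity": tn / (tn + fp),
        "PPV": tp / (tp + fp) if (tp + fp) else float("nan"),
        "NPV": tn / (tn + fn) if (tn + fn) else float("nan"),
    }
    if scores is not None:
        out["AUC"] = auc_score(y_true, scores)
    return out


def metrics_from_confusion(tp: int, fn: int, tn: int, fp: int) -> dict:
    """The five confusion-derived metrics straight from the counts."""
    return {
        "accuracy": (tp + tn) / (tp + tn + fp + fn),
        "sensitivity": tp / (tp + fn),
        "specificity": tn / (tn + fp),
        "PPV": tp / (tp + fp),
        "NPV": tn / (tn + fn),
    }


def run_experiment_matrix(
    group_tables: dict,
    labels,
    ratio: float = 0.7,
    seed: int = 0,
    classifiers=CLASSIFIER_KINDS,
    split=None,
) -> pd.DataFrame:
    """Evaluate every (group x classifier) cell on one shared split.

    ``group_tables`` maps group name -> subjects x features table (all on
    the same row index).  Unknown classifier kinds abort before any
    fitting.  A single classifier's failure is recorded as NaN metrics
    with the error message, not a panel failure.  The returned frame has
    one row per cell plus a ``best`` flag per group (highest AUC).
    """
    for kind in classifiers:
        if kind not in CLASSIFIER_KINDS:
            raise ValueError(f"unknown classifier {kind!r}")
    y = np.asarray(labels)
    if split is None:
        split = split_cohort(y, ratio=ratio, seed=seed)
    train_idx, test_idx = split
    rows = []
    for group, table in group_tables.items():
        X = np.asarray(table, dtype=float)
        for kind in classifiers:
            spec = ClassifierSpec(kind=kind, seed=seed)
            row = {"group": group, "classifier": kind,
                   "n_train": len(train_idx), "n_test": len(test_idx),
                   "n_features": X.shape[1]}
            try:
                pred, scores = fit_predict(spec, X[train_idx], y[train_idx], X[test_idx])
                row.update(compute_metrics(y[test_idx], pred, scores))
                row["error"] = ""
            except Exception as exc:  # one classifier failing is not fatal
                row.update({k: float("nan") for k in
                            ("TP", "FP", "TN", "FN", "accuracy", "sensitivity",
                             "specificity", "PPV", "NPV", "AUC")})
                row["error"] = str(exc)
            rows.append(row)
    report = pd.DataFrame(rows)
    report["best"] = False
    for group, sub in report.groupby("group"):
        if sub["AUC"].notna().any():
            report.loc[sub["AUC"].idxmax(), "best"] = True
    return report
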