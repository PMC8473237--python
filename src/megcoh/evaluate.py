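"""Classifier evaluation protocols.

Two protocols are implemented over k-NN, LDA and SVM:

* Monte-Carlo repetition (MCR): repeated stratified random observation-level
  splits (default 95%/5% per class, 20 repeats).  Epochs of one subject can
  land on both sides of a split, so this protocol is optimistic whenever
  features carry subject-specific structure.
* Subject-wise leave-one-out (LOO): fold f holds out the f-th subject of each
  class; no epoch of a held-out subject is ever seen in training.  This is
  the clinically honest protocol.

Reported metrics: per-fold accuracies, mean sensitivity and specificity with
MCI as the positive class, balanced accuracy = (sensitivity+specificity)/2,
and the rank-based (Mann-Whitney) AUC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features import FeatureDataset

logger = logging.getLogger(__name__)

POSITIVE_CLASS = 1  # MCI


@dataclass(frozen=True)
class ClassifierSpec:
    """Which classifier to run and how.

    ``family`` is one of ``knn``, ``lda``, ``svm``.  Protocol defaults follow
    the reported best performers: 3-NN for MCR, RBF-kernel SVM for LOO
    (poly2 and linear kernels are also available).  Features are z-scored
    with train-fit statistics before distance-based classifiers.
    """

    family: str = "knn"
    k: int = 3
    kernel: str = "rbf"  # rbf | poly2 | linear
    C: float = 1.0
    standardize: bool = True

    def validate(self):
        if self.family not in ("knn", "lda", "svm"):
            raise ValueError("family must be knn, lda or svm")
        if self.family == "knn" and (self.k < 1 or self.k % 2 == 0):
            raise ValueError("k must be odd for binary k-NN")
        if self.family == "svm" and self.kernel not in ("rbf", "poly2", "linear"):
            raise ValueError("kernel must be rbf, poly2 or linear")

    def build(self):
        self.validate()
        if self.family == "knn":
            clf = KNeighborsClassifier(n_neighbors=self.k)
        elif self.family == "lda":
            clf = LinearDiscriminantAnalysis()
        else:
            if self.kernel == "poly2":
                clf = SVC(kernel="poly", degree=2, C=self.C)
            else:
                clf = SVC(kernel=self.kernel, C=self.C)
        steps = []
        if self.standardize:
            steps.append(("scale", StandardScaler()))
        steps.append(("clf", clf))
        return Pipeline(steps)


MCR_DEFAULT = ClassifierSpec(family="knn", k=3)
LOO_DEFAULT = ClassifierSpec(family="svm", kernel="rbf")


@dataclass(frozen=True)
class SplitScheme:
    """Cross-validation scheme: MCR (repeated random splits) or subject LOO."""

    kind: str = "MCR"
    n_repeats: int = 20
    test_fraction: float = 0.05
    seed: int = 0

    def validate(self):
        if self.kind not in ("MCR", "LOO"):
            raise ValueError("kind must be MCR or LOO")
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test_fraction must be in (0,1)")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")


@dataclass
class EvalResult:
    """Aggregated evaluation outcome of one protocol/classifier run."""

    scheme: str
    accuracies: list
    mean_sensitivity: float
    mean_specificity: float
    balanced_accuracy: float
    auc: float
    confusion: dict  # pooled TP/FN/TN/FP over folds/repeats
    config: dict = field(default_factory=dict)
    subject_accuracy: float | None = None

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.accuracies))

    def to_dict(self) -> dict:
        return {
            "scheme": self.scheme,
            "accuracies": [float(a) for a in self.accuracies],
            "mean_accuracy": self.mean_accuracy,
            "mean_sensitivity": self.mean_sensitivity,
            "mean_specificity": self.mean_specificity,
            "balanced_accuracy": self.balanced_accuracy,
            "auc": self.auc,
            "confusion": self.confusion,
            "subject_accuracy": self.subject_accuracy,
            "config": self.config,
        }


def compute_metrics(tp: int, fn: int, tn: int, fp: int) -> dict:
    """Sensitivity/specificity/balanced accuracy from 2x2 counts (MCI positive).

    A zero denominator yields ``None`` for that rate (undefined), and the
    balanced accuracy is then undefined as well.
    """
    for v in (tp, fn, tn, fp):
        if v < 0:
            raise ValueError("confusion counts must be non-negative")
    if tp + fn + tn + fp == 0:
        raise ValueError("all-zero confusion matrix")
    sens = tp / (tp + fn) if (tp + fn) > 0 else None
    spec = tn / (tn + fp) if (tn + fp) > 0 else None
    bal = (sens + spec) / 2.0 if (sens is not None and spec is not None) else None
    return {"sensitivity": sens, "specificity": spec, "balanced_accuracy": bal}


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based AUC (Mann-Whitney normalization, midranks for ties)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int(np.sum(labels == POSITIVE_CLASS))
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes required for AUC")
    ranks = rankdata(scores)
    r_pos = ranks[labels == POSITIVE_CLASS].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def _scores(model, X: np.ndarray) -> np.ndarray:
    if hasattr(model, "decision_function"):
        try:
            return np.asarray(model.decision_function(X), dtype=float)
        except AttributeError:  # pragma: no cover
            pass
    return np.asarray(model.predict_proba(X)[:, 1], dtype=float)


def _fold_outcome(model, X_test, y_test):
    pred = model.predict(X_test)
    tp = int(np.sum((pred == 1) & (y_test == 1)))
    fn = int(np.sum((pred == 0) & (y_test == 1)))
    tn = int(np.sum((pred == 0) & (y_test == 0)))
    fp = int(np.sum((pred == 1) & (y_test == 0)))
    acc = float(np.mean(pred == y_test))
    return acc, (tp, fn, tn, fp), pred


def _aggregate(scheme, accs, folds, all_scores, all_labels, config, subject_acc=None):
    senss, specs = [], []
    n_undef = 0
    for tp, fn, tn, fp in folds:
        m = compute_metrics(tp, fn, tn, fp)
        if m["sensitivity"] is None or m["specificity"] is None:
            n_undef += 1
            continue
        senss.append(m["sensitivity"])
        specs.append(m["specificity"])
    if n_undef:
        logger.warning("%d fold(s) with undefined rates excluded from means", n_undef)
    mean_sens = float(np.mean(senss))
    mean_spec = float(np.mean(specs))
    pooled = np.sum(np.asarray(folds), axis=0)
    return EvalResult(
        scheme=scheme,
        accuracies=accs,
        mean_sensitivity=mean_sens,
        mean_specificity=mean_spec,
        balanced_accuracy=(mean_sens + mean_spec) / 2.0,
        auc=roc_auc(np.concatenate(all_scores), np.concatenate(all_labels)),
        confusion={
            "tp": int(pooled[0]),
            "fn": int(pooled[1]),
            "tn": int(pooled[2]),
            "fp": int(pooled[3]),
        },
        config=config,
        subject_accuracy=subject_acc,
    )


def mcr_evaluate(
    features: FeatureDataset,
    clf: ClassifierSpec = MCR_DEFAULT,
    scheme: SplitScheme | None = None,
) -> EvalResult:
    """Monte-Carlo repeated stratified random splits at the observation level.

    Per repeat, ``round(n_class * test_fraction)`` observations of each class
    (at least one) are held out; results are averaged over ``n_repeats``.
    """
    scheme = scheme or SplitScheme()
    scheme.validate()
    clf.validate()
    rng = np.random.default_rng(scheme.seed)
    X, y = features.X, features.y
    idx_by_class = [np.flatnonzero(y == c) for c in (0, 1)]
    for idx in idx_by_class:
        if idx.size < 2:
            raise ValueError("need at least 2 observations per class")
    accs, folds, all_scores, all_labels = [], [], [], []
    for _ in range(scheme.n_repeats):
        test_idx = []
        for idx in idx_by_class:
            n_test = max(1, int(round(idx.size * scheme.test_fraction)))
            test_idx.append(rng.choice(idx, size=n_test, replace=False))
        test_idx = np.concatenate(test_idx)
        mask = np.ones(y.size, dtype=bool)
        mask[test_idx] = False
        model = clf.build()
        model.fit(X[mask], y[mask])
        acc, counts, _ = _fold_outcome(model, X[test_idx], y[test_idx])
        accs.append(acc)
        folds.append(counts)
        all_scores.append(_scores(model, X[test_idx]))
        all_labels.append(y[test_idx])
    config = {"classifier": clf.__dict__, "scheme": scheme.__dict__}
    return _aggregate("MCR", accs, folds, all_scores, all_labels, config)


def loo_evaluate(
    features: FeatureDataset, clf: ClassifierSpec = LOO_DEFAULT
) -> EvalResult:
    """Subject-wise leave-one-out: fold f holds out subject f of each class.

    Epoch-level accuracy is averaged over folds; a subject-level
    majority-vote accuracy is reported alongside.
    """
    clf.validate()
    X, y, subj = features.X, features.y, features.subject_ids
    subjects = {c: sorted(set(subj[y == c])) for c in (0, 1)}
    if len(subjects[0]) != len(subjects[1]):
        raise ValueError("equal subject counts per class required for paired folds")
    if len(subjects[0]) < 2:
        raise ValueError("need at least 2 subjects per class")
    if set(subjects[0]) & set(subjects[1]):
        raise ValueError("a subject appears in both classes")
    accs, folds, all_scores, all_labels = [], [], [], []
    subj_correct = 0
    for f in range(len(subjects[0])):
        held = {subjects[0][f], subjects[1][f]}
        test_mask = np.isin(subj, list(held))
        train_mask = ~test_mask
        assert not (set(subj[train_mask]) & set(subj[test_mask]))
        model = clf.build()
        model.fit(X[train_mask], y[train_mask])
        acc, counts, pred = _fold_outcome(model, X[test_mask], y[test_mask])
        accs.append(acc)
        folds.append(counts)
        all_scores.append(_scores(model, X[test_mask]))
        all_labels.append(y[test_mask])
        # subject-level majority vote
        for s in held:
            m = subj[test_mask] == s
            vote = int(np.round(np.mean(pred[m])))
            subj_correct += int(vote == y[test_mask][m][0])
    config = {"classifier": clf.__dict__, "n_folds": len(subjects[0])}
    return _aggregate(
        "LOO",
        accs,
        folds,
        all_scores,
        all_labels,
        config,
        subject_acc=subj_correct / (2 * len(subjects[0])),
    )
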