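"""Emotion classification from PCA feature scores, with significance tests.

The contract mirrors a standard held-out evaluation: stratified 80/20
splitting done *before* any fitting, random-forest training with small-grid
stratified CV tuning, and a report carrying the confusion matrix, accuracy,
balanced accuracy (overall and per class), Cohen's kappa, one-vs-rest AUC,
the no-information rate, exact binomial and label-permutation p-values, and
Bonferroni-corrected pairwise Fisher exact tests on the confusion matrix.
Grouped cross-validation (leave-one-stimulus-out / leave-one-participant-
out) is provided for rating-prediction style analyses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.base import clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import (cohen_kappa_score, confusion_matrix,
                             recall_score, roc_auc_score)
from sklearn.model_selection import GridSearchCV, StratifiedKFold

log = logging.getLogger(__name__)

__all__ = [
    "ClassifierReport",
    "split_train_test",
    "train_classifier",
    "evaluate",
    "binomial_significance",
    "permutation_significance",
    "fisher_pairwise",
    "grouped_cross_validate",
]


@dataclass
class ClassifierReport:
    classes: list
    confusion: np.ndarray                 # rows = truth, cols = predicted
    accuracy: float
    balanced_accuracy: float              # mean per-class recall
    balanced_accuracy_per_class: dict     # (sensitivity + specificity) / 2
    kappa: float
    auc_per_class: dict
    auc_mean: float
    no_information_rate: float
    p_binomial: float = float("nan")
    p_permutation: float = float("nan")
    fisher_pairwise: dict = field(default_factory=dict)


def split_train_test(labels, frac: float = 0.8, seed: int = 0,
                     stratify_by=None) -> tuple[np.ndarray, np.ndarray]:
    """Stratified index split with per-class round-half-up train counts.

    With 76 trials per class and frac 0.8 this yields exactly 61 training
    and 15 test trials per class.  Returns (train_idx, test_idx), disjoint
    and exhaustive; the split is performed before any model fitting.
    """
    y = np.asarray(labels if stratify_by is None else stratify_by)
    rng = np.random.default_rng(seed)
    train, test = [], []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        if idx.size < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 trials")
        n_train = int(np.floor(frac * idx.size + 0.5))  # round half up
        perm = rng.permutation(idx)
        train.extend(perm[:n_train])
        test.extend(perm[n_train:])
    if not test:
        log.warning("train fraction %.2f leaves an empty test set", frac)
    return np.sort(np.array(train, dtype=int)), np.sort(np.array(test, dtype=int))


def train_classifier(scores: np.ndarray, labels, seed: int = 0,
                     cv_folds: int = 5):
    """Random forest tuned by stratified k-fold CV on balanced accuracy.

    The grid is deliberately small (trees x depth x features-per-split =
    3 x 3 x 2); the fitted ``GridSearchCV`` object is returned so both the
    best model and the CV table are available.
    """
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("training labels contain a single class")
    if counts.min() < cv_folds:
        raise ValueError("each class needs at least cv_folds samples")
    grid = {
        "n_estimators": [50, 100, 200],
        "max_depth": [None, 4, 8],
        "max_features": ["sqrt", None],
    }
    cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    search = GridSearchCV(
        RandomForestClassifier(random_state=seed),
        grid, scoring="balanced_accuracy", cv=cv, n_jobs=1, refit=True)
    search.fit(np.asarray(scores, dtype=float), y)
    return search


def binomial_significance(n_correct: int, n: int, p0: float) -> float:
    """Exact upper-tail binomial p: P(X >= n_correct | n, p0)."""
    if not 0 < p0 < 1:
        raise ValueError("p0 must lie strictly inside (0, 1)")
    if not 0 <= n_correct <= n:
        raise ValueError("n_correct must be in [0, n]")
    return float(stats.binom.sf(n_correct - 1, n, p0))


def permutation_significance(model, test_scores, test_labels,
                             n_perm: int = 1000, seed: int = 0) -> float:
    """Label-shuffling p-value with the add-one estimator.

    p = (1 + #{permuted accuracy >= observed}) / (n_perm + 1); predictions
    are computed once and compared against shuffled labels.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    y = np.asarray(test_labels)
    pred = model.predict(np.asarray(test_scores, dtype=float))
    observed = float(np.mean(pred == y))
    rng = np.random.default_rng(seed)
    hits = sum(float(np.mean(pred == rng.permutation(y))) >= observed
               for _ in range(n_perm))
    return (1 + hits) / (n_perm + 1)


def fisher_pairwise(confusion: np.ndarray, classes=None) -> dict:
    """Two-sided Fisher exact test per unordered class pair, Bonferroni x pairs.

    For pair (a, b) the 2x2 table is the confusion restricted to true and
    predicted labels in {a, b}; third-class predictions are ignored.
    """
    C = np.asarray(confusion)
    k = C.shape[0]
    classes = list(classes) if classes is not None else list(range(k))
    n_pairs = k * (k - 1) // 2
    out = {}
    for a in range(k):
        for b in range(a + 1, k):
            sub = np.array([[C[a, a], C[a, b]], [C[b, a], C[b, b]]], dtype=int)
            if sub.sum(axis=1).min() == 0 or sub.sum(axis=0).min() == 0:
                log.warning("empty margin for pair (%s, %s); p set to 1",
                            classes[a], classes[b])
                p = 1.0
            else:
                _, p = stats.fisher_exact(sub, alternative="two-sided")
            out[(classes[a], classes[b])] = min(1.0, float(p) * n_pairs)
    return out


def evaluate(model, test_scores, test_labels, n_perm: int = 1000,
             seed: int = 0) -> ClassifierReport:
    """Full held-out evaluation; fills every field of ClassifierReport."""
    X = np.asarray(test_scores, dtype=float)
    y = np.asarray(test_labels)
    if len(y) == 0:
        raise ValueError("test set is empty")
    classes = list(getattr(model, "classes_", np.unique(y)))
    unseen = set(y) - set(classes)
    if unseen:
        raise ValueError(f"test labels not seen in training: {unseen}")

    pred = model.predict(X)
    C = confusion_matrix(y, pred, labels=classes)
    n = C.sum()
    acc = float(np.trace(C)) / n
    bal = float(recall_score(y, pred, average="macro"))

    per_class = {}
    for i, cls in enumerate(classes):
        tp = C[i, i]
        fn = C[i].sum() - tp
        fp = C[:, i].sum() - tp
        tn = n - tp - fn - fp
        sens = tp / (tp + fn) if (tp + fn) else np.nan
        spec = tn / (tn + fp) if (tn + fp) else np.nan
        per_class[cls] = float((sens + spec) / 2)

    kappa = float(cohen_kappa_score(y, pred, labels=classes))

    auc_per_class, aucs = {}, []
    if hasattr(model, "predict_proba"):
        proba = model.predict_proba(X)
        for i, cls in enumerate(classes):
            truth = (y == cls).astype(int)
            if truth.min() == truth.max():
                auc_per_class[cls] = float("nan")
                continue
            a = float(roc_auc_score(truth, proba[:, i]))
            auc_per_class[cls] = a
            aucs.append(a)
    auc_mean = float(np.mean(aucs)) if aucs else float("nan")

    nir = float(np.unique(y, return_counts=True)[1].max() / n)
    p_binom = binomial_significance(int(np.trace(C)), int(n), nir)
    p_perm = permutation_significance(model, X, y, n_perm=n_perm, seed=seed)

    return ClassifierReport(
        classes=classes, confusion=C, accuracy=acc, balanced_accuracy=bal,
        balanced_accuracy_per_class=per_class, kappa=kappa,
        auc_per_class=auc_per_class, auc_mean=auc_mean,
        no_information_rate=nir, p_binomial=p_binom, p_permutation=p_perm,
        fisher_pairwise=fisher_pairwise(C, classes))


def grouped_cross_validate(scores, labels, groups, scheme: str = "LOSO",
                           seed: int = 0) -> dict:
    """Leave-one-group-out CV (LOSO over stimuli, LOPO over participants).

    Returns per-group accuracy, the mean accuracy, and the majority-class
    empirical chance baseline.
    """
    if scheme not in {"LOSO", "LOPO"}:
        raise ValueError("scheme must be LOSO or LOPO")
    X = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    g = np.asarray(groups)
    uniq = np.unique(g)
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    base = RandomForestClassifier(n_estimators=200, random_state=seed)
    per_group = {}
    for grp in uniq:
        hold = g == grp
        model = clone(base).fit(X[~hold], y[~hold])
        per_group[grp] = float(np.mean(model.predict(X[hold]) == y[hold]))
    _, counts = np.unique(y, return_counts=True)
    return {
        "scheme": scheme,
        "per_group": per_group,
        "mean_accuracy": float(np.mean(list(per_group.values()))),
        "chance_baseline": float(counts.max() / counts.sum()),
    }
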