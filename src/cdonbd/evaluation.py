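"""Cross-validated RBF-SVM classification and node-level group statistics.

Classification: subjects are split by seeded stratified k-fold (default
10).  Within each fold the template-distance features are recomputed from
the training subjects only (the caller supplies a feature builder), the
features are standardised on the training fold, an RBF-SVM is fit, and
the held-out subjects are scored.  Pooled out-of-fold predictions give a
single confusion matrix and the four headline metrics

    ACC = (TP+TN)/(TP+FP+TN+FN),  SEN = TP/(TP+FN),  SPE = TN/(TN+FP),

with AUC computed as the rank statistic on pooled decision-function
scores (probability a random positive outscores a random negative, ties
counted half).  The patient class is "positive" by convention, so SEN
measures patient detection.

Group statistics: per node, a two-sample Welch t-test on node distances
between the groups, Benjamini-Hochberg FDR correction across the n nodes,
and the display transform -log10(p_FDR); a node is significant when
p_FDR < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from statsmodels.stats.multitest import multipletests

from .exceptions import StratificationError, ValidationError

SIGNIFICANCE_LEVEL = 0.05


@dataclass
class FoldScheme:
    n_folds: int = 10
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValidationError("n_folds must be >= 2")


@dataclass
class SvmParams:
    C: float = 1.0
    gamma: float | str = "scale"  # "scale" = 1 / (n_features * feature variance)

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValidationError("C must be > 0")


@dataclass
class Metrics:
    ACC: float
    SEN: float
    SPE: float
    AUC: float
    confusion: tuple[int, int, int, int]  # (TP, TN, FP, FN)

    def to_dict(self) -> dict:
        tp, tn, fp, fn = self.confusion
        return {
            "ACC": self.ACC,
            "SEN": self.SEN,
            "SPE": self.SPE,
            "AUC": self.AUC,
            "TP": tp,
            "TN": tn,
            "FP": fp,
            "FN": fn,
        }


def rank_auc(scores: np.ndarray, is_positive: np.ndarray) -> float:
    """AUC as the Mann-Whitney rank statistic; ties count half."""
    scores = np.asarray(scores, dtype=float)
    is_positive = np.asarray(is_positive, dtype=bool)
    n_pos = int(is_positive.sum())
    n_neg = is_positive.size - n_pos
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    ranks = stats.rankdata(scores)
    return float((ranks[is_positive].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def metrics_from_confusion(
    TP: int,
    TN: int,
    FP: int,
    FN: int,
    scores: np.ndarray | None = None,
    is_positive: np.ndarray | None = None,
) -> Metrics:
    """Headline metrics from counts; undefined ratios are reported as NaN."""
    for name, v in (("TP", TP), ("TN", TN), ("FP", FP), ("FN", FN)):
        if v < 0:
            raise ValidationError(f"{name} must be nonnegative")
    total = TP + TN + FP + FN
    acc = (TP + TN) / total if total else float("nan")
    sen = TP / (TP + FN) if (TP + FN) else float("nan")
    spe = TN / (TN + FP) if (TN + FP) else float("nan")
    auc = rank_auc(scores, is_positive) if scores is not None else float("nan")
    return Metrics(acc, sen, spe, auc, (TP, TN, FP, FN))


FeatureBuilder = Callable[[np.ndarray], np.ndarray]


def crossval_classify(
    features: np.ndarray | FeatureBuilder,
    labels: Sequence[str],
    scheme: FoldScheme | None = None,
    svm: SvmParams | None = None,
    positive_label: str | None = None,
) -> Metrics:
    """Pooled out-of-fold metrics from stratified k-fold RBF-SVM.

    ``features`` is either a fixed (n_subjects, p) matrix or a callable
    mapping the training-subject indices to an (n_subjects, p) matrix —
    the hook through which templates are rebuilt per fold without leaking
    held-out subjects into template construction.
    """
    scheme = scheme or FoldScheme()
    svm = svm or SvmParams()
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValidationError(f"need exactly two classes, got {classes.tolist()}")
    if positive_label is None:
        positive_label = classes[1]
    if positive_label not in classes:
        raise ValidationError(f"positive_label {positive_label!r} not among {classes.tolist()}")
    y = (labels == positive_label).astype(int)
    n = labels.size
    if min(np.bincount(y)) < scheme.n_folds and scheme.stratified:
        raise StratificationError(
            f"need >= {scheme.n_folds} subjects per class for {scheme.n_folds}-fold "
            f"stratified CV, got counts {np.bincount(y).tolist()}"
        )

    splitter = StratifiedKFold(n_splits=scheme.n_folds, shuffle=True, random_state=scheme.seed)
    pred = np.full(n, -1, dtype=int)
    scores = np.zeros(n)
    for train_idx, test_idx in splitter.split(np.zeros(n), y):
        if np.unique(y[train_idx]).size < 2:
            raise StratificationError("training fold contains a single class")
        X = features(train_idx) if callable(features) else np.asarray(features, dtype=float)
        scaler = StandardScaler().fit(X[train_idx])
        clf = SVC(kernel="rbf", C=svm.C, gamma=svm.gamma)
        clf.fit(scaler.transform(X[train_idx]), y[train_idx])
        Xt = scaler.transform(X[test_idx])
        pred[test_idx] = clf.predict(Xt)
        scores[test_idx] = clf.decision_function(Xt)
    assert (pred >= 0).all(), "every subject must be predicted exactly once"

    tp = int(((pred == 1) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    return metrics_from_confusion(tp, tn, fp, fn, scores=scores, is_positive=y == 1)


def node_group_stats(
    distances_a: np.ndarray,
    distances_b: np.ndarray,
    node_labels: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-node Welch t-test between groups with BH-FDR correction.

    ``distances_a``/``distances_b`` are (subjects, nodes) arrays of node
    distances for the two groups.  Nodes with zero variance in both groups
    get p = 1 and are flagged in the ``degenerate`` column.
    """
    A = np.atleast_2d(np.asarray(distances_a, dtype=float))
    B = np.atleast_2d(np.asarray(distances_b, dtype=float))
    if A.shape[1] != B.shape[1]:
        raise ValidationError("groups must share the node dimension")
    if A.shape[0] < 2 or B.shape[0] < 2:
        raise ValidationError("need at least 2 subjects per group")
    n_nodes = A.shape[1]
    if node_labels is None:
        node_labels = [f"node_{i}" for i in range(n_nodes)]

    t_stat, p_raw = stats.ttest_ind(A, B, axis=0, equal_var=False)
    degenerate = (A.var(axis=0) == 0) & (B.var(axis=0) == 0)
    t_stat = np.where(degenerate, 0.0, t_stat)
    p_raw = np.where(degenerate, 1.0, p_raw)
    # equal constants in both groups also yield nan; treat as no evidence
    bad = ~np.isfinite(p_raw)
    t_stat = np.where(bad, 0.0, t_stat)
    p_raw = np.where(bad, 1.0, p_raw)

    _, p_fdr, _, _ = multipletests(p_raw, alpha=SIGNIFICANCE_LEVEL, method="fdr_bh")
    with np.errstate(divide="ignore"):
        neg_log_p = -np.log10(p_fdr)
    return pd.DataFrame(
        {
            "node_label": list(node_labels),
            "t": t_stat,
            "p": p_raw,
            "p_fdr": p_fdr,
            "neg_log_p": neg_log_p,
            "significant": p_fdr < SIGNIFICANCE_LEVEL,
            "degenerate": degenerate | bad,
        }
    )
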