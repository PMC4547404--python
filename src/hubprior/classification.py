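"""Disease-outcome classification from co-expression-difference features.

Each prioritized hub G contributes one feature per sample s:

    CoeDiff(G, s) = sum_i |x(Im_i, s) - x(G, s)|

over G's interactors Im_i (absolute differences by default; a
sign-preserving mode is available).  Predictability of the disease label is
assessed by leave-one-out cross-validation with a random-forest classifier:
each fold trains on n-1 samples and records the held-out sample's
disease-class vote fraction, and the n held-out scores yield a ROC curve
and its AUC (equal to the Mann–Whitney probability, ties counted half).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import LeaveOneOut

from .io_formats import DISEASE, ExpressionMatrix, GeneSet, SampleGroups
from .network_topology import InteractionNetwork

__all__ = [
    "FeatureMatrix",
    "ClassificationReport",
    "coediff_features",
    "loocv_evaluate",
    "roc_auc",
]


@dataclass
class FeatureMatrix:
    """Samples × hubs CoeDiff feature matrix with per-sample group labels."""

    values: pd.DataFrame  # index sample_id, columns hub ids
    labels: pd.Series  # sample_id -> disease/control


@dataclass
class ClassificationReport:
    """LOOCV held-out scores, ROC points and AUC."""

    scores: pd.Series  # per-sample held-out disease-class score
    labels: pd.Series
    roc_points: list[tuple[float, float]]  # (FPR, TPR)
    auc: float
    n_trees: int
    seed: int | None


def coediff_features(
    expr: ExpressionMatrix,
    groups: SampleGroups,
    net: InteractionNetwork,
    prioritized: GeneSet,
    absolute: bool = True,
) -> FeatureMatrix:
    """Per-sample CoeDiff feature vectors for the prioritized hubs.

    Hubs absent from the expression matrix raise; hubs without any
    interactor measured in the matrix are dropped with a warning-free skip
    (recorded by their absence).  Interactors missing from the matrix are
    ignored.
    """
    groups.validate_against(expr)
    row_of = {g: i for i, g in enumerate(expr.gene_ids)}
    X = expr.values.to_numpy(dtype=float)
    cols: dict[str, np.ndarray] = {}
    for hub in sorted(prioritized.genes):
        if hub not in row_of:
            raise KeyError(f"prioritized hub {hub!r} absent from expression matrix")
        if hub not in net:
            continue
        interactors = [row_of[n] for n in sorted(net.neighbors(hub)) if n in row_of]
        if not interactors:
            continue
        diff = X[interactors, :] - X[row_of[hub], :][None, :]
        cols[hub] = np.abs(diff).sum(axis=0) if absolute else diff.sum(axis=0)
    values = pd.DataFrame(cols, index=pd.Index(expr.sample_ids, name="sample_id"))
    labels = pd.Series(
        {s: groups.labels[s] for s in expr.sample_ids}, name="group"
    )
    return FeatureMatrix(values, labels)


def loocv_evaluate(
    features: FeatureMatrix, n_trees: int = 100, seed: int | None = None
) -> ClassificationReport:
    """Leave-one-out random-forest evaluation with ROC/AUC.

    Each of the n folds trains a fresh forest (same seed, so the report is
    reproducible) on the remaining n-1 samples; the held-out score is the
    fraction of trees voting for the disease class.
    """
    X = features.values.to_numpy(dtype=float)
    y = (features.labels.loc[features.values.index] == DISEASE).to_numpy()
    if len(np.unique(y)) < 2 or y.sum() < 2 or (~y).sum() < 2:
        raise ValueError("LOOCV needs at least 2 samples in each class")
    if X.shape[1] == 0:
        raise ValueError("feature matrix has no columns")
    scores = np.empty(len(y))
    for train_idx, test_idx in LeaveOneOut().split(X):
        clf = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
        clf.fit(X[train_idx], y[train_idx])
        disease_col = list(clf.classes_).index(True)
        scores[test_idx] = clf.predict_proba(X[test_idx])[:, disease_col]
    roc_points, auc = roc_auc(scores, y)
    return ClassificationReport(
        scores=pd.Series(scores, index=features.values.index, name="score"),
        labels=features.labels.loc[features.values.index],
        roc_points=roc_points,
        auc=auc,
        n_trees=n_trees,
        seed=seed,
    )


def roc_auc(
    scores: np.ndarray, labels: np.ndarray
) -> tuple[list[tuple[float, float]], float]:
    """ROC curve (descending-score threshold sweep) and Mann–Whitney AUC.

    *labels* are truthy for the positive (disease) class; both classes must
    be present.  Tied score pairs count one half.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    if y.all() or not y.any():
        raise ValueError("both classes must be present")
    fpr, tpr, _ = roc_curve(y, scores)
    auc = float(roc_auc_score(y, scores))
    return list(zip(fpr.tolist(), tpr.tolist())), auc
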