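"""LOOCV pattern classification of altered functional connectivity.

Features are Fisher-z ROI-pair correlations; classification is linear
(LDA or linear SVM) after per-fold standardization and dimensionality
reduction (PCA or linear-SVM RFE), evaluated by leave-one-out
cross-validation with the reducer and classifier fit strictly inside each
training fold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.decomposition import PCA
from sklearn.feature_selection import RFE
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .bwas import ROISet, VoxelTimeSeriesSet

__all__ = ["ROIFeatureTable", "ClassifierReport", "roi_pair_features", "loocv_classify", "roc_auc"]


def roi_pair_features(ts: VoxelTimeSeriesSet, rois: ROISet) -> pd.DataFrame:
    """Per-subject Fisher-z correlations between ROI-mean time series.

    Returns a table with ``subject_id``, ``group``, and one column per
    unordered ROI pair, named ``ROI{i}-ROI{j}`` with 1-based i < j, giving
    n_roi (n_roi - 1) / 2 features.
    """
    if len(rois) < 1:
        raise ValueError("need at least one ROI")
    for k, roi in enumerate(rois):
        if roi.size == 0:
            raise ValueError(f"ROI {k + 1} is empty")
    n_roi = len(rois)
    mean_ts = np.stack(
        [ts.data[:, :, roi.voxel_indices].mean(axis=2) for roi in rois], axis=2
    )  # (subjects, time, rois)
    iu = np.triu_indices(n_roi, k=1)
    names = [f"ROI{i + 1}-ROI{j + 1}" for i, j in zip(*iu)]
    rows = np.empty((ts.n_subjects, len(names)))
    for s in range(ts.n_subjects):
        r = np.corrcoef(mean_ts[s].T)[iu] if n_roi > 1 else np.empty(0)
        rows[s] = np.arctanh(np.clip(r, -1 + 1e-12, 1 - 1e-12))
    out = pd.DataFrame(rows, columns=names)
    out.insert(0, "group", ts.subjects["group"].to_numpy())
    out.insert(0, "subject_id", ts.subjects["subject_id"].to_numpy())
    return out


@dataclass
class ClassifierReport:
    accuracy: float
    sensitivity: float
    specificity: float
    auc: float
    folds: pd.DataFrame
    weights: np.ndarray
    feature_names: list
    model: str
    reducer: str
    reducer_dim: int
    pos_label: object = None
    confusion: dict = field(default_factory=dict)


def _make_reducer(reducer: str, dims, n_train: int, n_features: int, seed: int):
    if reducer == "pca":
        if dims is None:
            dims = 0.9  # fraction of variance retained within the fold
        if isinstance(dims, float) and 0 < dims < 1:
            return PCA(n_components=dims, svd_solver="full", random_state=seed)
        return PCA(n_components=min(int(dims), n_train - 1, n_features), random_state=seed)
    if reducer == "rfe":
        target = min(20 if dims is None else int(dims), n_features)
        return RFE(SVC(kernel="linear"), n_features_to_select=target, step=0.5)
    if reducer in (None, "none"):
        return None
    raise ValueError(f"unknown reducer {reducer!r}")


def _make_model(model: str, n_features: int, n_train: int):
    if model == "lda":
        if n_features >= n_train:
            # shrinkage keeps the within-class covariance invertible
            return LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
        return LinearDiscriminantAnalysis()
    if model == "svm":
        return SVC(kernel="linear")
    raise ValueError(f"unknown model {model!r}")


def loocv_classify(
    features: pd.DataFrame,
    model: str = "lda",
    reducer: str = "pca",
    dims=None,
    seed: int = 0,
    pos_label=None,
    feature_columns=None,
) -> ClassifierReport:
    """Leave-one-out cross-validated two-class linear classification.

    ``features`` must carry ``subject_id`` and ``group`` columns; remaining
    columns (or ``feature_columns``) are the feature vector.  Standardizer,
    reducer, and classifier are re-fit on each training fold only, so no
    information from the held-out subject leaks into its prediction.  The
    report aggregates held-out predictions (decision threshold 0 on the
    signed score) and the reported weight vector comes from a final fit on
    all subjects, back-projected to the original feature space.
    """
    if feature_columns is None:
        feature_columns = [c for c in features.columns if c not in ("subject_id", "group")]
    X = features[feature_columns].to_numpy(float)
    if np.isnan(X).any():
        raise ValueError("features contain missing values")
    y = features["group"].to_numpy()
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("exactly two classes required")
    if pos_label is None:
        pos_label = classes[-1]
    y_bin = (y == pos_label).astype(int)
    if y_bin.sum() < 2 or (1 - y_bin).sum() < 2:
        raise ValueError("each class needs at least 2 subjects")
    n = len(y)
    if dims is not None and not (isinstance(dims, float) and dims < 1) and int(dims) >= n - 1:
        raise ValueError("dims must be < n_subjects - 1")

    scores = np.empty(n)
    preds = np.empty(n, dtype=int)
    for i in range(n):
        tr = np.ones(n, dtype=bool)
        tr[i] = False
        if len(np.unique(y_bin[tr])) < 2:
            raise ValueError("a class is absent from a training fold")
        Xtr, ytr = X[tr], y_bin[tr]
        scaler = StandardScaler().fit(Xtr)
        Xtr_s = scaler.transform(Xtr)
        Xte_s = scaler.transform(X[i : i + 1])
        red = _make_reducer(reducer, dims, tr.sum(), X.shape[1], seed)
        if red is not None:
            red.fit(Xtr_s, ytr)
            Xtr_s = red.transform(Xtr_s)
            Xte_s = red.transform(Xte_s)
        clf = _make_model(model, Xtr_s.shape[1], tr.sum()).fit(Xtr_s, ytr)
        scores[i] = float(clf.decision_function(Xte_s)[0])
        preds[i] = int(scores[i] > 0)

    tp = int(((preds == 1) & (y_bin == 1)).sum())
    tn = int(((preds == 0) & (y_bin == 0)).sum())
    fp = int(((preds == 1) & (y_bin == 0)).sum())
    fn = int(((preds == 0) & (y_bin == 1)).sum())
    auc = roc_auc(scores, y_bin)

    # final model on all subjects for the reported weight map
    scaler = StandardScaler().fit(X)
    Xs = scaler.transform(X)
    red = _make_reducer(reducer, dims, n, X.shape[1], seed)
    if red is not None:
        red.fit(Xs, y_bin)
        Xr = red.transform(Xs)
    else:
        Xr = Xs
    clf = _make_model(model, Xr.shape[1], n).fit(Xr, y_bin)
    coef = np.ravel(clf.coef_)
    if isinstance(red, PCA):
        weights = red.components_.T @ coef
        dim = red.n_components_
    elif isinstance(red, RFE):
        weights = np.zeros(X.shape[1])
        weights[red.support_] = coef
        dim = int(red.n_features_)
    else:
        weights, dim = coef, X.shape[1]

    folds = pd.DataFrame(
        {
            "subject_id": features["subject_id"].to_numpy(),
            "true": y,
            "score": scores,
            "predicted": np.where(preds == 1, pos_label, classes[classes != pos_label][0]),
        }
    )
    return ClassifierReport(
        accuracy=(tp + tn) / n,
        sensitivity=tp / (tp + fn),
        specificity=tn / (tn + fp),
        auc=auc,
        folds=folds,
        weights=weights,
        feature_names=list(feature_columns),
        model=model,
        reducer=reducer if red is not None else "none",
        reducer_dim=dim,
        pos_label=pos_label,
        confusion={"tp": tp, "tn": tn, "fp": fp, "fn": fn},
    )


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve via the rank (Mann-Whitney) formulation.

    AUC is the probability that a random positive outranks a random
    negative, counting ties as one half: U / (n_pos * n_neg).
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    pos = labels == (1 if labels.dtype.kind in "biu" else np.unique(labels)[-1])
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(scores)
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))
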