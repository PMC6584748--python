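"""Linear-SVM multivariate pattern analysis of standardized ReHo maps.

Subjects are points in voxel space (one feature per in-mask voxel).  A linear
soft-margin SVM (C = 1, no inner tuning) is evaluated with
leave-one-subject-per-group-out cross-validation: each fold holds out one
patient and one control (paired positionally after a seeded shuffle), trains
on the rest, and records the held-out decision values.  Significance of the
cross-validated accuracy comes from a label-permutation null in which the
full LOOCV is re-run per relabelling.  The signed weight vector of a final
fit on all subjects, mapped back into the volume and thresholded to its
top-|w| fraction, is the discriminative map.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.svm import SVC

from .io import BrainMask
from .reho import ReHoMap

logger = logging.getLogger(__name__)

PATIENT, CONTROL = 1, -1


@dataclass
class FeatureMatrix:
    """N_subjects x V_voxels matrix with the voxel coordinate of each column."""

    matrix: np.ndarray
    voxel_index: np.ndarray  # (V, 3) int voxel coordinates, lexicographic order
    labels: np.ndarray       # +1 patient / -1 control
    subject_ids: list[str]
    affine: np.ndarray
    shape3d: tuple[int, int, int]

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if not np.isfinite(self.matrix).all():
            raise ValueError("feature matrix contains non-finite values")
        if set(np.unique(self.labels)) - {PATIENT, CONTROL}:
            raise ValueError("labels must be +1 (patient) or -1 (control)")
        if len(set(self.labels)) < 2:
            raise ValueError("both classes must be present")

    def to_volume(self, values: np.ndarray) -> np.ndarray:
        """Scatter a V-vector (a row, or a weight vector) back into the 3D grid."""
        vol = np.zeros(self.shape3d)
        vol[tuple(self.voxel_index.T)] = values
        return vol


def build_features(maps: list[ReHoMap], mask: BrainMask, labels,
                   subject_ids: list[str] | None = None) -> FeatureMatrix:
    """Stack per-subject maps into subjects x voxels, fixed lexicographic voxel order."""
    if mask.n_voxels == 0:
        raise ValueError("mask has no voxels")
    if len(maps) != len(labels):
        raise ValueError("one map per label required")
    for m in maps:
        mask.check_geometry(m)
    voxel_index = np.argwhere(mask.data)  # argwhere is lexicographic in (x, y, z)
    X = np.stack([m.data[mask.data] for m in maps])
    ids = subject_ids or [f"sub{i:03d}" for i in range(len(maps))]
    return FeatureMatrix(matrix=X, voxel_index=voxel_index,
                         labels=np.asarray(labels, dtype=int), subject_ids=list(ids),
                         affine=maps[0].affine, shape3d=mask.data.shape)


def train_linear_svm(X: np.ndarray, y: np.ndarray, C: float = 1.0):
    """Fit a soft-margin linear SVM; returns (fitted model, weights, bias)."""
    y = np.asarray(y)
    if len(set(y)) < 2:
        raise ValueError("training set contains a single class")
    model = SVC(kernel="linear", C=C, tol=1e-6)
    model.fit(X, y)
    return model, model.coef_.ravel().copy(), float(model.intercept_[0])


def loocv_pairs(labels: np.ndarray, seed: int = 0) -> list[np.ndarray]:
    """Leave-one-subject-per-group-out folds.

    The k-th patient is paired with the k-th control (positional pairing); a
    single seeded permutation shuffles the fold order, identically for both
    groups, so fold composition is invariant under a global label flip.  With
    unequal group sizes the leftover subjects of the larger group are held
    out singly in extra folds.  Every subject appears in exactly one test set.
    """
    labels = np.asarray(labels)
    pat = np.flatnonzero(labels == PATIENT)
    con = np.flatnonzero(labels == CONTROL)
    if len(pat) < 2 or len(con) < 2:
        raise ValueError("each group needs at least 2 subjects for LOOCV")
    rng = np.random.default_rng(seed)
    n_pairs = min(len(pat), len(con))
    order = rng.permutation(n_pairs)
    folds = [np.array([pat[k], con[k]]) for k in order]
    for idx in list(pat[n_pairs:]) + list(con[n_pairs:]):
        folds.append(np.array([idx]))
    return folds


@dataclass
class SvmReport:
    fold_predictions: np.ndarray
    decision_values: np.ndarray
    accuracy: float      # percent
    sensitivity: float   # percent, patient = positive class
    specificity: float   # percent
    auc: float
    roc_points: np.ndarray  # (n, 2) of (FPR, TPR)
    weight_map: np.ndarray  # 3D signed weights from the all-subject refit
    mean_fold_weight_map: np.ndarray
    bias: float
    labels: np.ndarray
    subject_ids: list[str]
    permutation_p: float | None = None

    def confusion(self) -> dict[str, int]:
        y, yhat = self.labels, self.fold_predictions
        return {
            "TP": int(((y == PATIENT) & (yhat == PATIENT)).sum()),
            "TN": int(((y == CONTROL) & (yhat == CONTROL)).sum()),
            "FP": int(((y == CONTROL) & (yhat == PATIENT)).sum()),
            "FN": int(((y == PATIENT) & (yhat == CONTROL)).sum()),
        }


def _loocv_accuracy(X: np.ndarray, y: np.ndarray, folds: list[np.ndarray],
                    C: float) -> tuple[np.ndarray, np.ndarray]:
    """Run LOOCV; returns (predictions, decision values) per subject."""
    n = len(y)
    preds = np.zeros(n, dtype=int)
    decs = np.zeros(n)
    for test_idx in folds:
        train = np.ones(n, dtype=bool)
        train[test_idx] = False
        model, _, _ = train_linear_svm(X[train], y[train], C=C)
        d = model.decision_function(X[test_idx])
        # sklearn orients decision_function toward classes_[1]; flip if needed
        if model.classes_[1] != PATIENT:
            d = -d
        decs[test_idx] = d
        preds[test_idx] = np.where(d > 0, PATIENT, CONTROL)
    return preds, decs


def svm_loocv(features: FeatureMatrix, C: float = 1.0, seed: int = 0) -> SvmReport:
    """Leave-one-per-group-out evaluation of the linear SVM.

    The reported weight map comes from a refit on all subjects; the mean of
    the per-fold weight vectors is kept alongside and their correlation logged.
    """
    X, y = features.matrix, features.labels
    folds = loocv_pairs(y, seed=seed)
    preds, decs = _loocv_accuracy(X, y, folds, C)

    n = len(y)
    tp = ((y == PATIENT) & (preds == PATIENT)).sum()
    tn = ((y == CONTROL) & (preds == CONTROL)).sum()
    accuracy = 100.0 * (tp + tn) / n
    sensitivity = 100.0 * tp / max((y == PATIENT).sum(), 1)
    specificity = 100.0 * tn / max((y == CONTROL).sum(), 1)

    fpr, tpr, _ = roc_curve(y, decs, pos_label=PATIENT)
    auc = float(roc_auc_score(y == PATIENT, decs))

    # final weights: all-subject refit, plus mean per-fold weights for comparison
    _, w_full, bias = train_linear_svm(X, y, C=C)
    fold_ws = []
    for test_idx in folds:
        train = np.ones(n, dtype=bool)
        train[test_idx] = False
        _, w, _ = train_linear_svm(X[train], y[train], C=C)
        fold_ws.append(w)
    w_mean = np.mean(fold_ws, axis=0)
    if w_full.std() > 0 and w_mean.std() > 0:
        logger.info("weight-map correlation (refit vs mean-fold): %.4f",
                    np.corrcoef(w_full, w_mean)[0, 1])

    return SvmReport(fold_predictions=preds, decision_values=decs,
                     accuracy=float(accuracy), sensitivity=float(sensitivity),
                     specificity=float(specificity), auc=auc,
                     roc_points=np.column_stack([fpr, tpr]),
                     weight_map=features.to_volume(w_full),
                     mean_fold_weight_map=features.to_volume(w_mean),
                     bias=bias, labels=y.copy(),
                     subject_ids=list(features.subject_ids))


def permutation_test(features: FeatureMatrix, n_perm: int = 1000, seed: int = 0,
                     C: float = 1.0, observed_accuracy: float | None = None) -> float:
    """Label-permutation p-value of the LOOCV accuracy.

    Each replicate shuffles all labels once and re-runs the entire LOOCV;
    ``p = (1 + #{perm accuracy >= observed}) / (n_perm + 1)``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    X, y = features.matrix, features.labels
    if observed_accuracy is None:
        observed_accuracy = svm_loocv(features, C=C, seed=seed).accuracy
    rng = np.random.default_rng(seed)
    count = 0
    n = len(y)
    for _ in range(n_perm):
        y_perm = rng.permutation(y)
        if len(set(y_perm)) < 2:
            continue
        folds = loocv_pairs(y_perm, seed=int(rng.integers(2 ** 31)))
        preds, _ = _loocv_accuracy(X, y_perm, folds, C)
        acc = 100.0 * (preds == y_perm).mean()
        if acc >= observed_accuracy - 1e-12:
            count += 1
    return float(1 + count) / (n_perm + 1)


@dataclass
class DiscriminativeMap:
    weights: np.ndarray        # 3D signed weights on retained voxels, 0 elsewhere
    retained_fraction: float
    retained_voxels: np.ndarray  # (k, 3)


def discriminative_map(weights: np.ndarray, voxel_index: np.ndarray,
                       shape3d: tuple[int, int, int],
                       fraction: float = 0.30,
                       mode: str = "rank-fraction") -> DiscriminativeMap:
    """Threshold the signed weight vector to its most discriminative voxels.

    ``rank-fraction`` (default): retain the ``round(fraction * V)`` voxels of
    largest |w| (ties at the cutoff broken by lexicographic voxel order).
    ``value-fraction``: retain voxels with |w| >= fraction * max|w|.
    Positive weights mean higher values in patients.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must be in (0, 1]")
    weights = np.asarray(weights, dtype=float)
    if not np.isfinite(weights).all():
        raise ValueError("weights contain non-finite values")
    V = len(weights)
    absw = np.abs(weights)
    if mode == "rank-fraction":
        k = int(round(fraction * V))
        k = max(k, 1)
        # stable sort on (-|w|) keeps lexicographic voxel order within ties
        order = np.argsort(-absw, kind="stable")
        keep_idx = np.sort(order[:k])
    elif mode == "value-fraction":
        keep_idx = np.flatnonzero(absw >= fraction * absw.max())
    else:
        raise ValueError("mode must be 'rank-fraction' or 'value-fraction'")
    vol = np.zeros(shape3d)
    kept = voxel_index[keep_idx]
    vol[tuple(kept.T)] = weights[keep_idx]
    return DiscriminativeMap(weights=vol, retained_fraction=fraction,
                             retained_voxels=kept)


def discriminative_peaks(dmap: DiscriminativeMap, affine: np.ndarray,
                         top: int = 10) -> pd.DataFrame:
    """Strongest retained voxels as a table of mm coordinates and signed weights."""
    vals = dmap.weights[tuple(dmap.retained_voxels.T)]
    order = np.argsort(-np.abs(vals))[:top]
    rows = []
    for i in order:
        vox = dmap.retained_voxels[i]
        mm = (np.asarray(affine) @ np.append(vox, 1.0))[:3]
        rows.append({"x_mm": mm[0], "y_mm": mm[1], "z_mm": mm[2],
                     "weight": float(vals[i]),
                     "direction": "patient>control" if vals[i] > 0 else "patient<control"})
    return pd.DataFrame(rows)
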