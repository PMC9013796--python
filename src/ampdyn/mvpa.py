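"""Multivariate pattern analysis: LOOCV linear-SVM classification,
support-vector regression for prognosis, sensitivity maps, and
permutation-based inference with max-statistic family-wise correction.

Classification follows the leave-one-out protocol: each subject in turn is
held out, a linear soft-margin SVM (C = 1) is trained on the rest, and the
held-out subject is scored 100 (correct) or 0 (wrong); the mean over folds
is the cross-validated accuracy.  Per-fold primal weight vectors are
back-projected to voxel space; a positive weight marks a voxel whose
elevation favours the patient class.  Significance comes from permutation
nulls (labels reshuffled, the full LOOCV re-run); region-wise analyses use
the distribution of the per-permutation *maximum* statistic across regions,
which controls the family-wise error over regions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._svm import (
    loocv_decision_values,
    loocv_predictions_svr,
    permuted_loocv_accuracies,
    permuted_loocv_pearson,
    svc_fit,
    svr_fit,
)

log = logging.getLogger("ampdyn")

DEFAULT_C = 1.0
DEFAULT_EPSILON = 0.1


@dataclass
class FeatureMatrix:
    """Subjects x features, with a back-map from columns to voxel coords."""

    X: np.ndarray
    coords: np.ndarray  # (n_features, 3) int voxel coordinates
    subject_ids: np.ndarray | None = None
    grid_shape: tuple[int, int, int] | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if not np.isfinite(self.X).all():
            raise ValueError("feature matrix contains non-finite values")

    @property
    def n_subjects(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]


@dataclass
class CVResult:
    """Pooled leave-one-out results (classification or regression)."""

    predictions: np.ndarray
    truths: np.ndarray
    fold_accuracies: np.ndarray | None = None  # 100 or 0 per fold
    mean_accuracy_pct: float | None = None
    decision_values: np.ndarray | None = None
    auc: float | None = None
    pearson_r: float | None = None
    rmse: float | None = None


@dataclass
class SensitivityMap:
    """Classifier weights per voxel, averaged over folds.

    `consistency_mask` marks features whose weight sign is identical in
    every fold; only those are interpreted.
    """

    mean_weights: np.ndarray
    fold_weights: np.ndarray  # (n_folds, n_features)
    consistency_mask: np.ndarray
    coords: np.ndarray
    grid_shape: tuple[int, int, int] | None = None

    def consistency_over_folds(self, n_folds: int) -> np.ndarray:
        """Sign-consistency mask using only the first `n_folds` folds."""
        sg = np.sign(self.fold_weights[:n_folds])
        return (np.abs(sg.sum(axis=0)) == n_folds) & (sg != 0).all(axis=0)

    def to_volume(self, which: str = "mean") -> np.ndarray:
        if self.grid_shape is None:
            raise ValueError("grid shape unknown")
        vol = np.zeros(self.grid_shape)
        vals = self.mean_weights if which == "mean" else self.consistency_mask.astype(float)
        vol[tuple(self.coords.T)] = vals
        return vol


@dataclass
class PermutationNull:
    observed: float
    null_values: np.ndarray
    p_value: float
    n_perm: int


def extract_features(maps, mask_or_labels, region_label: int | None = None) -> FeatureMatrix:
    """Build a subjects x voxels matrix from a map stack and a mask.

    `maps` is an (n_subjects, x, y, z) array or a list of AmplitudeMaps;
    `mask_or_labels` a boolean mask or an integer label image combined with
    `region_label`.  Columns follow lexicographic voxel order.
    """
    if not isinstance(maps, np.ndarray):
        maps = np.stack([m.data for m in maps], axis=0)
    maps = np.asarray(maps, dtype=float)
    lab = np.asarray(mask_or_labels)
    mask = (lab == region_label) if region_label is not None else lab.astype(bool)
    if mask.shape != maps.shape[1:]:
        raise ValueError("mask shape does not match map grid")
    if not mask.any():
        raise ValueError("empty mask")
    coords = np.argwhere(mask)  # C order == lexicographic by coordinate
    X = maps[:, mask]
    return FeatureMatrix(X, coords, grid_shape=maps.shape[1:])


def _pm1(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {classes}")
    return np.where(y == classes.max(), 1.0, -1.0)


def loocv_classify(
    X: FeatureMatrix | np.ndarray, y, C: float = DEFAULT_C
) -> tuple[CVResult, SensitivityMap]:
    """Leave-one-out linear-SVM classification with sensitivity maps.

    A decision value of exactly 0 predicts the positive (patient) class.
    """
    fm = X if isinstance(X, FeatureMatrix) else FeatureMatrix(np.asarray(X), np.zeros((np.asarray(X).shape[1], 3), dtype=int))
    ypm = _pm1(y)
    n = fm.n_subjects
    if n < 4:
        raise ValueError("need at least 4 subjects")
    if len(ypm) != n:
        raise ValueError("label count mismatch")
    K = fm.X @ fm.X.T
    dec = np.empty(n)
    fold_w = np.empty((n, fm.n_features))
    idx = np.arange(n)
    for i in range(n):
        tr = idx != i
        ytr = ypm[tr]
        if len(np.unique(ytr)) < 2:
            raise ValueError(f"training fold {i} contains a single class")
        coef, b = svc_fit(np.ascontiguousarray(K[np.ix_(tr, tr)]), ytr, C)
        dec[i] = K[i, tr] @ coef + b
        fold_w[i] = fm.X[tr].T @ coef
    pred = np.where(dec >= 0, 1.0, -1.0)
    fold_acc = np.where(pred == ypm, 100.0, 0.0)
    sg = np.sign(fold_w)
    consistency = (np.abs(sg.sum(axis=0)) == n) & (sg != 0).all(axis=0)
    _, auc = roc_curve_auc(dec, ypm)
    cv = CVResult(
        predictions=pred,
        truths=ypm,
        fold_accuracies=fold_acc,
        mean_accuracy_pct=float(fold_acc.mean()),
        decision_values=dec,
        auc=auc,
    )
    sens = SensitivityMap(
        mean_weights=fold_w.mean(axis=0),
        fold_weights=fold_w,
        consistency_mask=consistency,
        coords=fm.coords,
        grid_shape=fm.grid_shape,
    )
    return cv, sens


def roc_curve_auc(decision_values, labels) -> tuple[np.ndarray, float]:
    """ROC points and AUC by the rank (Mann-Whitney) formulation, ties averaged."""
    dec = np.asarray(decision_values, dtype=float)
    ypm = _pm1(labels)
    pos = ypm > 0
    n_pos = int(pos.sum())
    n_neg = len(ypm) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(dec)
    auc = (ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    order = np.argsort(-dec, kind="stable")
    tps = np.cumsum(pos[order])
    fps = np.cumsum(~pos[order])
    # collapse threshold ties, prepend the (0, 0) point
    keep = np.r_[np.diff(dec[order]) != 0, True]
    points = np.column_stack(
        [np.r_[0.0, fps[keep] / n_neg], np.r_[0.0, tps[keep] / n_pos]]
    )
    return points, float(auc)


def _loocv_accuracy(K: np.ndarray, ypm: np.ndarray, C: float) -> float:
    dec = loocv_decision_values(K, ypm, C)
    pred = np.where(dec >= 0, 1.0, -1.0)
    return float((pred == ypm).mean())


def _loocv_r(K: np.ndarray, target: np.ndarray, C: float, eps: float) -> float:
    pred = loocv_predictions_svr(K, target, C, eps)
    if pred.std() == 0 or target.std() == 0:
        return 0.0
    return float(np.corrcoef(pred, target)[0, 1])


def permutation_test(
    X,
    y,
    statistic: str = "accuracy",
    n_perm: int = 1000,
    seed: int = 0,
    C: float = DEFAULT_C,
    epsilon: float = DEFAULT_EPSILON,
    statistic_fn=None,
) -> PermutationNull:
    """Permutation null of a full-LOOCV statistic.

    `statistic` is "accuracy" (classification; labels shuffled) or "r"
    (SVR; targets shuffled); alternatively `statistic_fn(Xarr, y_perm)`
    computes an arbitrary statistic.  p = proportion of null values >= the
    observed one, floored at 1/n_perm (never exactly 0).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    Xarr = X.X if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)
    rng = np.random.default_rng(seed)
    if statistic_fn is not None:
        observed = float(statistic_fn(Xarr, np.asarray(y)))
        null = np.array(
            [float(statistic_fn(Xarr, rng.permutation(np.asarray(y)))) for _ in range(n_perm)]
        )
    else:
        K = Xarr @ Xarr.T
        if statistic == "accuracy":
            ypm = _pm1(y)
            observed = _loocv_accuracy(K, ypm, C)
            perms = np.stack([rng.permutation(ypm) for _ in range(n_perm)])
            null = permuted_loocv_accuracies(K, perms, C)
        elif statistic == "r":
            target = np.asarray(y, dtype=float)
            observed = _loocv_r(K, target, C, epsilon)
            perms = np.stack([rng.permutation(target) for _ in range(n_perm)])
            null = permuted_loocv_pearson(K, perms, C, epsilon)
        else:
            raise ValueError("statistic must be 'accuracy' or 'r'")
    p = max(float((null >= observed).mean()), 1.0 / n_perm)
    return PermutationNull(float(observed), null, p, n_perm)


def loocv_svr(
    X, target, C: float = DEFAULT_C, epsilon: float = DEFAULT_EPSILON
) -> CVResult:
    """Leave-one-out linear epsilon-SVR: pooled predictions, Pearson r, RMSE."""
    Xarr = X.X if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)
    target = np.asarray(target, dtype=float)
    n = Xarr.shape[0]
    if n < 5:
        raise ValueError("need at least 5 subjects")
    if target.std() == 0:
        raise ValueError("constant target")
    K = Xarr @ Xarr.T
    pred = loocv_predictions_svr(K, target, C, epsilon)
    r = float(np.corrcoef(pred, target)[0, 1]) if pred.std() > 0 else 0.0
    rmse = float(np.sqrt(np.mean((pred - target) ** 2)))
    return CVResult(predictions=pred, truths=target, pearson_r=r, rmse=rmse)


def _region_features(maps: np.ndarray, atlas: np.ndarray, mask) -> dict[int, np.ndarray]:
    out = {}
    for lab in np.unique(atlas):
        if lab == 0:
            continue
        sel = atlas == lab
        if mask is not None:
            sel &= mask
        if sel.sum() < 1:
            log.warning("region %d empty after masking; skipped", lab)
            continue
        out[int(lab)] = maps[:, sel]
    return out


def regionwise_classify(
    maps,
    y,
    atlas: np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
    C: float = DEFAULT_C,
    alpha: float = 0.05,
    mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-region LOOCV accuracy with max-statistic FWE-corrected p-values.

    One shared label shuffle per permutation is applied to every region; the
    null is the per-permutation maximum accuracy across regions, so each
    region's corrected p accounts for the search over regions.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if not isinstance(maps, np.ndarray):
        maps = np.stack([m.data for m in maps], axis=0)
    ypm = _pm1(y)
    regions = _region_features(np.asarray(maps, dtype=float), np.asarray(atlas), mask)
    if not regions:
        raise ValueError("atlas contains no usable regions")
    rng = np.random.default_rng(seed)
    perms = np.stack([rng.permutation(ypm) for _ in range(n_perm)])
    labs = sorted(regions)
    obs = np.empty(len(labs))
    nulls = np.empty((len(labs), n_perm))
    for k, lab in enumerate(labs):
        Xr = regions[lab]
        K = Xr @ Xr.T
        obs[k] = _loocv_accuracy(K, ypm, C)
        nulls[k] = permuted_loocv_accuracies(K, perms, C)
    max_null = nulls.max(axis=0)
    p_fwe = np.maximum((max_null[None, :] >= obs[:, None]).mean(axis=1), 1.0 / n_perm)
    return pd.DataFrame(
        {
            "region": labs,
            "n_voxels": [regions[lab].shape[1] for lab in labs],
            "accuracy_pct": obs * 100.0,
            "p_fwe": p_fwe,
            "significant": p_fwe < alpha,
        }
    )


def regionwise_predict(
    maps,
    target,
    atlas: np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
    C: float = DEFAULT_C,
    epsilon: float = DEFAULT_EPSILON,
    alpha: float = 0.05,
    mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-region LOOCV-SVR correlation with max-statistic FWE correction.

    As `regionwise_classify`, with the statistic the Pearson correlation
    between leave-one-out predictions and the true target, and the target
    vector shuffled per permutation (shared across regions).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if not isinstance(maps, np.ndarray):
        maps = np.stack([m.data for m in maps], axis=0)
    target = np.asarray(target, dtype=float)
    regions = _region_features(np.asarray(maps, dtype=float), np.asarray(atlas), mask)
    if not regions:
        raise ValueError("atlas contains no usable regions")
    rng = np.random.default_rng(seed)
    perms = np.stack([rng.permutation(target) for _ in range(n_perm)])
    labs = sorted(regions)
    obs = np.empty(len(labs))
    nulls = np.empty((len(labs), n_perm))
    for k, lab in enumerate(labs):
        Xr = regions[lab]
        K = Xr @ Xr.T
        obs[k] = _loocv_r(K, target, C, epsilon)
        nulls[k] = permuted_loocv_pearson(K, perms, C, epsilon)
    max_null = nulls.max(axis=0)
    p_fwe = np.maximum((max_null[None, :] >= obs[:, None]).mean(axis=1), 1.0 / n_perm)
    return pd.DataFrame(
        {
            "region": labs,
            "n_voxels": [regions[lab].shape[1] for lab in labs],
            "pearson_r": obs,
            "p_fwe": p_fwe,
            "significant": p_fwe < alpha,
        }
    )
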