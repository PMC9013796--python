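"""Voxel-wise covariate-adjusted group comparison with cluster-level
permutation correction.

Per voxel, the map value is regressed on [intercept, group, age, gender,
education]; the t statistic of the group coefficient (df = n - 5) forms the
statistic map.  Family-wise error over clusters is controlled by a
permutation cluster-extent test: suprathreshold clusters (|t| above the
two-sided voxel threshold, 26-connectivity) are compared against the null
distribution of the maximum cluster extent under group-label permutation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

CONNECTIVITY_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class DesignInfo:
    """Group indicator plus the three adjustment covariates."""

    group: np.ndarray  # 1 = patient, 0 = control
    age: np.ndarray
    gender: np.ndarray  # 0/1
    education: np.ndarray

    def __post_init__(self) -> None:
        for name in ("group", "age", "gender", "education"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        n = len(self.group)
        if any(len(getattr(self, f)) != n for f in ("age", "gender", "education")):
            raise ValueError("design columns must have equal length")
        if not np.isfinite(np.column_stack([self.age, self.gender, self.education])).all():
            raise ValueError("missing covariate values")
        if (self.group == 1).sum() < 2 or (self.group == 0).sum() < 2:
            raise ValueError("both groups need at least 2 subjects")

    @classmethod
    def from_cohort(cls, table: pd.DataFrame) -> "DesignInfo":
        return cls(
            group=(table["group"].to_numpy() == "patient").astype(float),
            age=table["age"].to_numpy(dtype=float),
            gender=table["gender"].to_numpy(dtype=float),
            education=table["education"].to_numpy(dtype=float),
        )

    def matrix(self, group: np.ndarray | None = None) -> np.ndarray:
        g = self.group if group is None else group
        return np.column_stack(
            [np.ones(len(g)), g, self.age, self.gender, self.education]
        )


@dataclass
class Cluster:
    voxels: np.ndarray  # (k, 3) int coordinates
    peak_t: float
    peak_coord: tuple[int, int, int]
    extent: int
    p_corrected: float


@dataclass
class ClusterSet:
    clusters: list
    t_threshold: float
    n_perm: int
    df: int


def _group_t_flat(Y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """t statistic of the group column (index 1) for Y (n, voxels)."""
    n, p = X.shape
    XtX = X.T @ X
    if np.linalg.matrix_rank(XtX) < p:
        # name the offending columns for the caller
        names = ["intercept", "group", "age", "gender", "education"][:p]
        bad = []
        keep: list[int] = []
        rank = 0
        for k in range(p):
            r = np.linalg.matrix_rank(X[:, keep + [k]])
            if r > rank:
                keep.append(k)
                rank = r
            else:
                bad.append(names[k])
        raise ValueError(f"collinear design columns: {bad}")
    XtXinv = np.linalg.inv(XtX)
    beta = XtXinv @ (X.T @ Y)
    resid = Y - X @ beta
    dof = n - p
    sigma2 = (resid * resid).sum(axis=0) / dof
    se = np.sqrt(np.maximum(sigma2 * XtXinv[1, 1], 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta[1] / se, 0.0)
    return t


def voxelwise_group_t(
    maps: np.ndarray, design: DesignInfo, mask: np.ndarray | None = None
) -> np.ndarray:
    """Covariate-adjusted two-sample t-map from a (n_subjects, x, y, z) stack."""
    maps = np.asarray(maps, dtype=float)
    n = maps.shape[0]
    if n != len(design.group):
        raise ValueError("subject count mismatch between maps and design")
    Y = maps.reshape(n, -1)
    t = _group_t_flat(Y, design.matrix()).reshape(maps.shape[1:])
    if mask is not None:
        t = np.where(mask, t, 0.0)
    return t


def _max_cluster_extent(binary: np.ndarray) -> int:
    labels, n = ndimage.label(binary, structure=CONNECTIVITY_26)
    if n == 0:
        return 0
    return int(np.bincount(labels.ravel())[1:].max())


def cluster_correct(
    tmap: np.ndarray,
    design: DesignInfo,
    maps: np.ndarray,
    p_voxel: float = 0.001,
    alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
    mask: np.ndarray | None = None,
) -> ClusterSet:
    """Permutation cluster-extent FWE correction of a voxel-wise t-map.

    Suprathreshold voxels are |t| > t_crit at the two-sided `p_voxel` level;
    26-connected components form clusters.  The null distribution is the
    maximum cluster extent over `n_perm` random permutations of the group
    labels (covariates stay attached to their subjects).  Each observed
    cluster's corrected p is the fraction of null maxima at least as large
    (floored at 1/n_perm); clusters with p <= alpha are returned.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    maps = np.asarray(maps, dtype=float)
    n = maps.shape[0]
    dof = n - 5
    t_crit = stats.t.isf(p_voxel / 2.0, dof)
    supra = np.abs(tmap) > t_crit
    if mask is not None:
        supra &= mask
    labels, n_clust = ndimage.label(supra, structure=CONNECTIVITY_26)
    if n_clust == 0:
        return ClusterSet([], t_crit, n_perm, dof)

    Y = maps.reshape(n, -1)
    rng = np.random.default_rng(seed)
    null_max = np.empty(n_perm)
    for q in range(n_perm):
        perm_group = rng.permutation(design.group)
        tq = _group_t_flat(Y, design.matrix(perm_group)).reshape(tmap.shape)
        sq = np.abs(tq) > t_crit
        if mask is not None:
            sq &= mask
        null_max[q] = _max_cluster_extent(sq)

    clusters = []
    for lab in range(1, n_clust + 1):
        vox = np.argwhere(labels == lab)
        extent = len(vox)
        p_corr = max(float((null_max >= extent).mean()), 1.0 / n_perm)
        if p_corr <= alpha:
            tvals = tmap[labels == lab]
            peak_i = int(np.abs(tvals).argmax())
            clusters.append(
                Cluster(
                    voxels=vox,
                    peak_t=float(tvals[peak_i]),
                    peak_coord=tuple(int(c) for c in vox[peak_i]),
                    extent=extent,
                    p_corrected=p_corr,
                )
            )
    clusters.sort(key=lambda c: -c.extent)
    return ClusterSet(clusters, t_crit, n_perm, dof)


def extract_cluster_means(maps: np.ndarray, cluster: Cluster) -> np.ndarray:
    """Per-subject mean map value over a cluster's voxels."""
    if cluster.extent == 0 or len(cluster.voxels) == 0:
        raise ValueError("empty cluster")
    maps = np.asarray(maps, dtype=float)
    ix, iy, iz = cluster.voxels.T
    return maps[:, ix, iy, iz].mean(axis=1)


def correlate_clinical(values: np.ndarray, clinical: np.ndarray) -> tuple[float, float]:
    """Pearson correlation with two-sided p from the t transform (n-2 df)."""
    values = np.asarray(values, dtype=float)
    clinical = np.asarray(clinical, dtype=float)
    if len(values) != len(clinical) or len(values) < 3:
        raise ValueError("need >= 3 paired finite observations")
    if not (np.isfinite(values).all() and np.isfinite(clinical).all()):
        raise ValueError("non-finite values")
    if values.std() == 0 or clinical.std() == 0:
        raise ValueError("zero variance in one of the vectors")
    r, p = stats.pearsonr(values, clinical)
    return float(r), float(p)
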