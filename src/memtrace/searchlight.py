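"""ROI-constrained volumetric searchlight with permutation cluster inference.

Instead of fixed-radius spheres, each searchlight region grows outwards
from a centre voxel within the ROI until it holds a fixed number of voxels
(default 160), so regions hug the ROI boundary.  Within each region a
memory-by-memory similarity matrix is built exactly as in the whole-ROI
analysis and compared by Spearman rank correlation against a model matrix
with ones on the diagonal (a memory resembles itself) and zeros elsewhere.
Each voxel's map value is the average agreement over every region it
belongs to.

Group inference is nonparametric: per-voxel one-sample t maps are
thresholded (default t >= 3), clusters are 26-connected components, and a
null distribution of the maximum cluster size is built by randomly
sign-flipping whole subject maps, giving cluster-level family-wise-error
corrected p values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.stats import rankdata, spearmanr

from memtrace.glm import PatternMatrix
from memtrace.rsa import memory_rsm

DEFAULT_REGION_SIZE = 160

#: 26-neighbourhood connectivity (SPM convention) for cluster labelling.
CONNECTIVITY = np.ones((3, 3, 3), dtype=bool)


@dataclass
class VoxelRegion:
    """A grown searchlight region: centre, members, saturation flag."""

    center: tuple[int, int, int]
    members: np.ndarray  # (m, 3) voxel coordinates
    saturated: bool  # True when the ROI was smaller than the target size


@dataclass
class ClusterResult:
    """Suprathreshold clusters with FWE-corrected p values."""

    clusters: pd.DataFrame  # cluster_id, n_voxels, peak_t, p_fwe, peak_ijk
    labels: np.ndarray  # 3-D int label image (0 = background)
    n_permutations: int
    t_threshold: float
    null_max_sizes: np.ndarray


def _linear_index(coords: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Ascending linear index, 0-based, x-fastest (Fortran order)."""
    return np.ravel_multi_index(coords.T, shape, order="F")


def roi_coordinates(roi_mask: np.ndarray) -> np.ndarray:
    """In-mask voxel coordinates ordered by ascending linear index (x-fastest).

    This ordering defines the package-wide correspondence between pattern
    columns and mask voxels.
    """
    coords = np.argwhere(np.asarray(roi_mask, dtype=bool))
    if len(coords) == 0:
        raise ValueError("ROI mask is empty")
    return coords[np.argsort(_linear_index(coords, roi_mask.shape))]


def grow_region(
    roi_mask: np.ndarray,
    center: tuple[int, int, int],
    target: int = DEFAULT_REGION_SIZE,
) -> VoxelRegion:
    """Grow a fixed-size region around ``center`` within the ROI.

    ROI voxels are sorted by Euclidean distance from the centre (voxel
    units), distance ties broken by ascending linear index, and the nearest
    ``target`` voxels taken.  An ROI smaller than the target returns the
    whole ROI with the saturation flag set.
    """
    mask = np.asarray(roi_mask, dtype=bool)
    center = tuple(int(c) for c in center)
    if not mask[center]:
        raise ValueError(f"center voxel {center} lies outside the ROI")
    coords = roi_coordinates(mask)
    dist = np.linalg.norm(coords - np.array(center), axis=1)
    order = np.lexsort((_linear_index(coords, mask.shape), dist))
    if len(coords) < target:
        members = coords[order]
        return VoxelRegion(center=center, members=members, saturated=True)
    return VoxelRegion(center=center, members=coords[order[:target]], saturated=False)


def _model_agreement(rsm_block: np.ndarray) -> float:
    """Spearman rho between the lower triangle (with diagonal) and identity."""
    m = rsm_block.shape[0]
    tri = np.tril_indices(m)
    neural = rsm_block[tri]
    model = np.eye(m)[tri]
    if np.all(neural == neural[0]) or not np.all(np.isfinite(neural)):
        return np.nan
    rho, _ = spearmanr(neural, model)
    return float(rho)


def region_rsm_score(
    p: PatternMatrix | np.ndarray,
    trials: pd.DataFrame,
    per_set: bool = True,
) -> float:
    """Model-RSM agreement for one region's patterns.

    Builds the memory similarity matrix from the region's voxels
    (cross-session trial pairs, as in the whole-ROI analysis) and returns
    the Spearman correlation with the identity-model matrix.  By default
    the two memory sets are scored as separate 8 x 8 matrices and the two
    correlations averaged; degenerate (constant) matrices yield NaN, which
    callers must treat as missing rather than zero.
    """
    pat = p.data if isinstance(p, PatternMatrix) else np.asarray(p, dtype=float)
    if per_set:
        rhos = []
        for set_label in sorted(trials["set"].unique()):
            sel = (trials["set"] == set_label).to_numpy()
            rsm = memory_rsm(pat[sel], trials[sel])
            rhos.append(_model_agreement(rsm.matrix))
        rhos = [r for r in rhos if np.isfinite(r)]
        return float(np.mean(rhos)) if rhos else np.nan
    rsm = memory_rsm(pat, trials)
    return _model_agreement(rsm.matrix)


def searchlight_map(
    p: PatternMatrix | np.ndarray,
    trials: pd.DataFrame,
    roi_mask: np.ndarray,
    target: int = DEFAULT_REGION_SIZE,
    per_set: bool = True,
) -> np.ndarray:
    """Per-voxel mean model agreement over every region the voxel joins.

    Pattern columns must follow the package voxel ordering (ascending
    linear index within the mask).  Returns a 3-D map with NaN outside the
    ROI; every ROI voxel is covered by at least its own centred region.
    """
    mask = np.asarray(roi_mask, dtype=bool)
    coords = roi_coordinates(mask)
    pat = p.data if isinstance(p, PatternMatrix) else np.asarray(p, dtype=float)
    if pat.shape[1] != len(coords):
        raise ValueError(
            f"pattern voxel count {pat.shape[1]} does not match ROI size {len(coords)}"
        )
    lin = _linear_index(coords, mask.shape)
    col_of = {l: i for i, l in enumerate(lin)}

    sums = np.zeros(len(coords))
    counts = np.zeros(len(coords))
    for center in coords:
        region = grow_region(mask, tuple(center), target)
        cols = np.array(
            [col_of[l] for l in _linear_index(region.members, mask.shape)]
        )
        rho = region_rsm_score(pat[:, cols], trials, per_set=per_set)
        if np.isfinite(rho):
            sums[cols] += rho
            counts[cols] += 1
    values = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    out = np.full(mask.shape, np.nan)
    out[tuple(coords.T)] = values
    return out


def _t_map(maps: np.ndarray) -> np.ndarray:
    """Per-voxel one-sample t across subjects (axis 0)."""
    n = maps.shape[0]
    mean = maps.mean(axis=0)
    sd = maps.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        return mean / (sd / np.sqrt(n))


def _max_cluster_size(t_vals: np.ndarray, mask: np.ndarray, thresh: float) -> int:
    supra = np.zeros(mask.shape, dtype=bool)
    supra[mask] = t_vals >= thresh
    if not supra.any():
        return 0
    labels, n = ndimage.label(supra, structure=CONNECTIVITY)
    if n == 0:
        return 0
    return int(np.max(ndimage.sum_labels(supra, labels, index=np.arange(1, n + 1))))


def signflip_cluster_test(
    maps: list[np.ndarray],
    roi_mask: np.ndarray,
    n_perm: int = 10000,
    t_thresh: float = 3.0,
    alpha: float = 0.05,
    seed: int | np.random.Generator = 0,
    fisher: bool = False,
    signs: np.ndarray | None = None,
) -> ClusterResult:
    """Cluster-level FWE inference by subject-wise sign flipping.

    Observed clusters are 26-connected components of voxels with one-sample
    t >= ``t_thresh``.  The null distribution of the maximum cluster size
    comes from ``n_perm`` random sign assignments over whole subject maps
    (the identity assignment included, so corrected p >= 1/n_perm);
    corrected p for a cluster is the proportion of null maxima at least as
    large as its size.
    """
    import warnings

    mask = np.asarray(roi_mask, dtype=bool)
    if len(maps) < 6:
        raise ValueError("need at least 6 subject maps for sign-flip inference")
    if signs is not None:
        n_perm = len(signs)
    if n_perm < 100:
        warnings.warn(
            f"n_perm={n_perm} gives a very coarse p granularity of {1 / n_perm:.3f}",
            stacklevel=2,
        )
    data = np.stack([m[mask] for m in maps])  # subjects x roi voxels
    if np.isnan(data).any():
        raise ValueError("subject maps contain NaN inside the ROI")
    if fisher:
        data = np.arctanh(np.clip(data, -1 + 1e-12, 1 - 1e-12))
    n_subj, n_vox = data.shape

    t_obs = _t_map(data)
    supra = np.zeros(mask.shape, dtype=bool)
    supra[mask] = np.nan_to_num(t_obs) >= t_thresh
    labels, n_clust = ndimage.label(supra, structure=CONNECTIVITY)

    if signs is None:
        rng = np.random.default_rng(seed)
        signs = rng.choice([-1.0, 1.0], size=(n_perm, n_subj))
        signs[0] = 1.0  # identity assignment anchors the null
    else:
        signs = np.asarray(signs, dtype=float)
        if signs.shape[1] != n_subj:
            raise ValueError("explicit sign matrix must have one column per subject")
        n_perm = signs.shape[0]
    sumsq = np.sum(data**2, axis=0)  # invariant under sign flips
    null_max = np.zeros(n_perm, dtype=int)
    for i in range(n_perm):
        mean = signs[i] @ data / n_subj
        var = (sumsq - n_subj * mean**2) / (n_subj - 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t_perm = mean / np.sqrt(var / n_subj)
        null_max[i] = _max_cluster_size(np.nan_to_num(t_perm), mask, t_thresh)

    coords_c = np.argwhere(mask)  # row order matches boolean indexing
    rows = []
    for cid in range(1, n_clust + 1):
        in_cluster = labels == cid
        size = int(in_cluster.sum())
        p_fwe = float(np.mean(null_max >= size))
        cluster_t = np.where(in_cluster[mask], t_obs, -np.inf)
        peak_col = int(np.argmax(cluster_t))
        peak_ijk = tuple(int(v) for v in coords_c[peak_col])
        rows.append(
            {
                "cluster_id": cid,
                "n_voxels": size,
                "peak_t": float(t_obs[peak_col]),
                "p_fwe": p_fwe,
                "peak_ijk": peak_ijk,
                "significant": p_fwe < alpha,
            }
        )
    clusters = pd.DataFrame(
        rows,
        columns=["cluster_id", "n_voxels", "peak_t", "p_fwe", "peak_ijk", "significant"],
    )
    return ClusterResult(
        clusters=clusters,
        labels=labels,
        n_permutations=n_perm,
        t_threshold=t_thresh,
        null_max_sizes=null_max,
    )
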