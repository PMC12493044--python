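"""Voxel-based lesion-symptom mapping with TFCE permutation inference.

Pipeline: binary lesion masks on a common grid are mirrored across the
laterality axis (voxelwise OR with the reflected mask, boosting power when
there is no laterality hypothesis), voxels damaged in fewer than
``min_patients`` patients are excluded, and at every remaining voxel a
pooled-variance two-sample t statistic compares the behavioural scores of
damaged vs spared patients (signed so that a damage-associated decrease in
the score is negative). The t map is enhanced with threshold-free cluster
enhancement (TFCE): each voxel accumulates extent^E * height^H * dh over
cluster-forming thresholds, separately for the positive and negative tails,
with 6-connected clusters. Family-wise inference permutes the behavioural
scores across patients and compares each voxel's |TFCE| against the
permutation distribution of the map-wise maximum |TFCE|; the per-map alpha
is Bonferroni-corrected across the behavioural regressors (0.05 / 3 for the
three recipient contrasts).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "LesionMask",
    "VLSMResult",
    "mirror_and_binarize",
    "coverage_filter",
    "voxelwise_stat",
    "tfce",
    "permutation_vlsm",
    "bonferroni_alpha",
    "save_mask",
    "load_mask",
    "cluster_summary",
]

#: 6-neighbour connectivity in 3-D (faces only)
_STRUCT = ndimage.generate_binary_structure(3, 1)


def bonferroni_alpha(alpha: float = 0.05, n_regressors: int = 3) -> float:
    """Per-map significance level corrected across behavioural regressors."""
    return alpha / n_regressors


@dataclass
class LesionMask:
    """Binary 3-D damage grid for one patient."""

    data: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    laterality_axis: int = 0
    patient_id: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("lesion mask must be a 3-D grid")
        vals = np.unique(self.data)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("lesion mask must be binary (0/1)")
        self.data = self.data.astype(np.uint8)


def _stack(masks: list[LesionMask]) -> np.ndarray:
    if not masks:
        raise ValueError("empty lesion cohort")
    shape = masks[0].data.shape
    for m in masks:
        if m.data.shape != shape:
            raise ValueError("all masks in a cohort must share one grid shape")
    return np.stack([m.data for m in masks]).astype(np.uint8)


def mirror_and_binarize(mask: LesionMask) -> LesionMask:
    """Voxelwise OR of the mask with its reflection across the laterality axis.

    The output is symmetric and idempotent under repeated application. The
    grid must have even or odd symmetric extent along the axis (any size
    works: reflection is a simple flip of the full axis).
    """
    axis = mask.laterality_axis
    if not 0 <= axis < 3:
        raise ValueError(f"laterality axis must be 0..2, got {axis}")
    mirrored = np.flip(mask.data, axis=axis)
    return LesionMask(
        data=np.maximum(mask.data, mirrored),
        voxel_size=mask.voxel_size,
        laterality_axis=axis,
        patient_id=mask.patient_id,
    )


def coverage_filter(masks: list[LesionMask], min_patients: int = 5) -> np.ndarray:
    """Boolean inclusion mask: voxels damaged in >= ``min_patients`` patients."""
    stacked = _stack(masks)
    return stacked.sum(axis=0) >= min_patients


def _t_columns(damage: np.ndarray, scores: np.ndarray):
    """Pooled-variance two-sample t per column of a patients x voxels matrix.

    Sign convention: mean(damaged) - mean(spared), so scores that drop with
    damage give negative t. Columns where either group is empty or the
    pooled variance vanishes are set to 0 (returned in the ``degenerate``
    flag array).
    """
    p = damage.shape[0]
    n1 = damage.sum(axis=0)
    n0 = p - n1
    s1 = damage.T @ scores
    s1sq = damage.T @ scores**2
    tot = scores.sum()
    totsq = (scores**2).sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        m1 = s1 / n1
        m0 = (tot - s1) / n0
        ss1 = s1sq - n1 * m1**2
        ss0 = (totsq - s1sq) - n0 * m0**2
        df = n1 + n0 - 2
        sp2 = (ss1 + ss0) / df
        se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n0))
        t = (m1 - m0) / se
    degenerate = (n1 == 0) | (n0 == 0) | ~np.isfinite(t)
    t = np.where(degenerate, 0.0, t)
    return t, degenerate


def voxelwise_stat(
    masks: list[LesionMask],
    scores: np.ndarray,
    inclusion: np.ndarray | None = None,
    min_patients: int = 5,
) -> np.ndarray:
    """Map of two-sample t statistics (damaged vs spared) at included voxels.

    Excluded voxels are 0.
    """
    scores = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("behavioural scores must be finite")
    stacked = _stack(masks)
    if len(scores) != stacked.shape[0]:
        raise ValueError("one score per patient required")
    if inclusion is None:
        inclusion = coverage_filter(masks, min_patients)
    flat = stacked.reshape(stacked.shape[0], -1)[:, inclusion.ravel()]
    t, _ = _t_columns(flat.astype(float), scores)
    out = np.zeros(inclusion.shape, dtype=float)
    out[inclusion] = t
    return out


def _tfce_one_tail(stat: np.ndarray, E: float, H: float, dh: float) -> np.ndarray:
    out = np.zeros_like(stat, dtype=float)
    top = float(stat.max(initial=0.0))
    n_thresh = int(np.floor(top / dh + 1e-9))
    for k in range(1, n_thresh + 1):
        h = k * dh
        bw = stat >= h
        labels, n = ndimage.label(bw, structure=_STRUCT)
        if n:
            sizes = np.bincount(labels.ravel())
            incr = (sizes.astype(float) ** E) * (h**H) * dh
            incr[0] = 0.0
            out += incr[labels]
    return out


def tfce(
    stat_map: np.ndarray,
    E: float = 0.5,
    H: float = 2.0,
    dh: float | None = None,
    n_steps: int = 100,
) -> np.ndarray:
    """Threshold-free cluster enhancement of a signed statistic map.

    TFCE(v) = sum over thresholds h = dh, 2dh, ... of
    extent(cluster containing v at h)^E * h^H * dh, evaluated separately on
    the positive map and on its negation (clusters are 6-connected); the
    result carries the sign of the input tail. ``dh`` defaults to
    max|stat| / n_steps.
    """
    stat_map = np.asarray(stat_map, dtype=float)
    if not np.all(np.isfinite(stat_map)):
        raise ValueError("stat map must be finite")
    peak = float(np.abs(stat_map).max(initial=0.0))
    if peak == 0.0:
        return np.zeros_like(stat_map)
    if dh is None:
        dh = peak / n_steps
    if dh <= 0:
        raise ValueError("dh must be positive")
    pos = _tfce_one_tail(np.maximum(stat_map, 0.0), E, H, dh)
    neg = _tfce_one_tail(np.maximum(-stat_map, 0.0), E, H, dh)
    return pos - neg


@dataclass
class VLSMResult:
    regressor: str
    inclusion: np.ndarray  # bool, coverage >= min_patients
    t_map: np.ndarray
    tfce_map: np.ndarray
    p_map: np.ndarray  # 1.0 outside the inclusion mask
    significant: np.ndarray  # bool, p < alpha_corrected within inclusion
    null_max_tfce: np.ndarray
    n_permutations: int
    seed: int
    alpha_corrected: float


def permutation_vlsm(
    masks: list[LesionMask],
    scores: np.ndarray,
    n_permutations: int = 5000,
    seed: int = 0,
    alpha_corrected: float | None = None,
    *,
    min_patients: int = 5,
    E: float = 0.5,
    H: float = 2.0,
    n_steps: int = 100,
    regressor: str = "score",
) -> VLSMResult:
    """Whole-map permutation test on the max |TFCE| statistic.

    The null distribution is the map-wise maximum |TFCE| under random
    permutation of the behavioural scores across patients; each included
    voxel's p-value is (1 + #{null >= observed |TFCE|}) / (n_permutations
    + 1), giving family-wise error control. ``alpha_corrected`` defaults to
    0.05/3 for the three recipient-contrast regressors.
    """
    if n_permutations < 100:
        raise ValueError("use at least 100 permutations")
    scores = np.asarray(scores, dtype=float)
    if np.ptp(scores) == 0:
        raise ValueError("behavioural scores are constant; permutation null is degenerate")
    if alpha_corrected is None:
        alpha_corrected = bonferroni_alpha()
    stacked = _stack(masks)
    if len(scores) != stacked.shape[0]:
        raise ValueError("one score per patient required")
    inclusion = stacked.sum(axis=0) >= min_patients
    shape = inclusion.shape

    # crop to the inclusion bounding box: TFCE cost scales with grid volume
    if not inclusion.any():
        zero = np.zeros(shape)
        return VLSMResult(
            regressor=regressor,
            inclusion=inclusion,
            t_map=zero,
            tfce_map=zero.copy(),
            p_map=np.ones(shape),
            significant=np.zeros(shape, dtype=bool),
            null_max_tfce=np.zeros(n_permutations),
            n_permutations=n_permutations,
            seed=seed,
            alpha_corrected=alpha_corrected,
        )
    bbox = tuple(
        slice(int(ix.min()), int(ix.max()) + 1) for ix in np.nonzero(inclusion)
    )
    incl_c = inclusion[bbox]
    flat = stacked.reshape(stacked.shape[0], -1)[:, inclusion.ravel()].astype(float)

    def stat_cube(score_vec):
        t, _ = _t_columns(flat, score_vec)
        cube = np.zeros(incl_c.shape)
        cube[incl_c] = t
        return cube

    t_obs = stat_cube(scores)
    peak = float(np.abs(t_obs).max(initial=0.0))
    dh = peak / n_steps if peak > 0 else 1.0
    tfce_obs = tfce(t_obs, E=E, H=H, dh=dh)

    rng = np.random.default_rng(seed)
    null = np.empty(n_permutations)
    for i in range(n_permutations):
        perm = rng.permutation(len(scores))
        t_perm = stat_cube(scores[perm])
        null[i] = np.abs(tfce(t_perm, E=E, H=H, dh=dh)).max(initial=0.0)

    null_sorted = np.sort(null)
    obs_abs = np.abs(tfce_obs[incl_c])
    n_ge = n_permutations - np.searchsorted(null_sorted, obs_abs, side="left")
    p_vals = (1.0 + n_ge) / (n_permutations + 1.0)

    p_map = np.ones(shape)
    t_map = np.zeros(shape)
    tfce_map = np.zeros(shape)
    p_map[inclusion] = p_vals
    t_map[bbox] = t_obs
    tfce_map[bbox] = tfce_obs
    significant = (p_map < alpha_corrected) & inclusion
    return VLSMResult(
        regressor=regressor,
        inclusion=inclusion,
        t_map=t_map,
        tfce_map=tfce_map,
        p_map=p_map,
        significant=significant,
        null_max_tfce=null,
        n_permutations=n_permutations,
        seed=seed,
        alpha_corrected=alpha_corrected,
    )


def cluster_summary(result: VLSMResult) -> pd.DataFrame:
    """Significant clusters: peak coordinate, peak |t|, extent, peak p."""
    labels, n = ndimage.label(result.significant, structure=_STRUCT)
    rows = []
    for lab in range(1, n + 1):
        sel = labels == lab
        abs_t = np.where(sel, np.abs(result.t_map), -np.inf)
        peak = np.unravel_index(int(np.argmax(abs_t)), abs_t.shape)
        rows.append(
            {
                "cluster": lab,
                "extent_voxels": int(sel.sum()),
                "peak_x": peak[0],
                "peak_y": peak[1],
                "peak_z": peak[2],
                "peak_t": float(result.t_map[peak]),
                "peak_p": float(result.p_map[peak]),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "cluster",
            "extent_voxels",
            "peak_x",
            "peak_y",
            "peak_z",
            "peak_t",
            "peak_p",
        ],
    )


# ---------------------------------------------------------------------------
# NIfTI I/O (masks share a common affine; synthetic grids use identity)


def save_mask(mask: LesionMask, path, affine: np.ndarray | None = None) -> None:
    import nibabel as nib

    if affine is None:
        affine = np.diag(list(mask.voxel_size) + [1.0])
    nib.save(nib.Nifti1Image(mask.data.astype(np.uint8), affine), str(path))


def save_map(data: np.ndarray, path, affine: np.ndarray | None = None) -> None:
    """Write a float result map (t, TFCE or p) as NIfTI."""
    import nibabel as nib

    if affine is None:
        affine = np.eye(4)
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine), str(path))


def load_mask(path, laterality_axis: int = 0, patient_id: str = "") -> LesionMask:
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    data = (data > 0.5).astype(np.uint8)
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return LesionMask(
        data=data,
        voxel_size=zooms,
        laterality_axis=laterality_axis,
        patient_id=patient_id,
    )
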