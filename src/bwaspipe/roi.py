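"""Atlas-anchored ROI definition and ROI-wise FC group testing.

ROIs are atlas regions holding at least a minimum number of significant
voxels; each ROI's time series is the unweighted mean BOLD signal over
its *significant* voxels only. ROI-pair FC differences are tested with
the same covariate-adjusted group GLM as the link stage, with
Benjamini-Hochberg FDR control across all pairs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from bwaspipe.bwas import _group_glm, group_vector, pair_indices
from bwaspipe.errors import AlignmentError, DataError
from bwaspipe.types import MAMap, ROI, ROISet, VoxelCohort


def define_rois(
    significant_coords: np.ndarray,
    ma: MAMap,
    atlas_volume: np.ndarray,
    labels: pd.DataFrame,
    min_voxels: int = 20,
) -> ROISet:
    """Group significant voxels by atlas label; keep regions with
    >= ``min_voxels`` of them.

    The per-region peak is the member voxel with the highest MA (ties
    broken by lowest linear grid index); its world coordinate is taken
    through the MA map's affine.
    """
    atlas_volume = np.asarray(atlas_volume)
    if atlas_volume.shape != ma.mask.shape:
        raise AlignmentError(
            f"atlas shape {atlas_volume.shape} does not match grid "
            f"{ma.mask.shape}"
        )
    significant_coords = np.asarray(significant_coords, dtype=np.int64).reshape(
        -1, 3
    )
    name_of = dict(zip(labels["region_id"].astype(int), labels["name"]))
    rois: list[ROI] = []
    if len(significant_coords) == 0:
        return ROISet(rois=rois)
    # sort members by linear index so argmax tie-breaking is deterministic
    lin = np.ravel_multi_index(significant_coords.T, atlas_volume.shape)
    order = np.argsort(lin)
    significant_coords = significant_coords[order]
    vox_labels = atlas_volume[tuple(significant_coords.T)]
    ma_vol = ma.to_volume()
    for rid in np.unique(vox_labels):
        if rid <= 0:
            continue
        coords = significant_coords[vox_labels == rid]
        if len(coords) < min_voxels:
            continue
        values = ma_vol[tuple(coords.T)]
        peak_local = int(np.argmax(values))
        peak_coord = coords[peak_local]
        peak_world = (ma.affine @ np.append(peak_coord, 1.0))[:3]
        rois.append(
            ROI(
                region_id=int(rid),
                name=name_of.get(int(rid), f"region_{int(rid)}"),
                voxel_coords=coords,
                peak_ma=int(values[peak_local]),
                peak_coord=peak_coord,
                peak_world=peak_world,
            )
        )
    return ROISet(rois=rois)


def roi_timeseries(subject_data: np.ndarray, mask: np.ndarray, roi: ROI) -> np.ndarray:
    """Mean time series over an ROI's member voxels for one subject.

    ``subject_data`` is the masked (n_voxels, T) matrix in ascending
    linear-index voxel order.
    """
    if roi.n_voxels == 0:
        raise DataError(f"ROI {roi.name!r} has no member voxels")
    lin = np.ravel_multi_index(roi.voxel_coords.T, mask.shape)
    mask_lin = np.flatnonzero(mask.ravel())
    pos = np.searchsorted(mask_lin, lin)
    if np.any(pos >= len(mask_lin)) or np.any(mask_lin[pos] != lin):
        raise DataError(f"ROI {roi.name!r} has voxels outside the mask")
    return subject_data[pos].mean(axis=0)


def roi_fc_matrix(cohort: VoxelCohort, rois: ROISet) -> pd.DataFrame:
    """Per-subject Fisher-z FC for every ROI pair.

    Returns a long-format table (subject_id, roi_a, roi_b, r, z).
    """
    if len(rois) < 2:
        raise DataError("need at least 2 ROIs for pairwise FC")
    series = np.stack(
        [
            [roi_timeseries(cohort.data[s], cohort.mask, roi) for roi in rois]
            for s in range(cohort.n_subjects)
        ]
    )  # (n_subjects, n_rois, T)
    iu, ju = pair_indices(len(rois))
    rows = []
    for s, sid in enumerate(cohort.subject_ids):
        x = series[s]
        sd = x.std(axis=1)
        if np.any(sd == 0):
            raise DataError(f"constant ROI series for subject {sid!r}")
        xc = (x - x.mean(axis=1, keepdims=True)) / sd[:, None]
        r = (xc @ xc.T) / x.shape[1]
        r_pairs = np.clip(r[iu, ju], -0.999999, 0.999999)
        for k in range(len(iu)):
            rows.append(
                {
                    "subject_id": sid,
                    "roi_a": rois.names[iu[k]],
                    "roi_b": rois.names[ju[k]],
                    "r": r_pairs[k],
                    "z": np.arctanh(r_pairs[k]),
                }
            )
    return pd.DataFrame(rows)


def bh_fdr(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    adjusted_(k) = min over r >= k of (m * p_(r) / r), capped at 1;
    preserves the ranking of the inputs.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise DataError("p_values must be one-dimensional")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise DataError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def roi_group_fc_test(
    cohort: VoxelCohort,
    rois: ROISet,
    phenotype: pd.DataFrame,
    covariates: tuple[str, ...] | list[str] = ("age", "education", "mean_fd", "itv"),
    q: float = 0.05,
) -> pd.DataFrame:
    """Covariate-adjusted group test on every ROI-pair Fisher-z FC with
    BH-FDR across pairs.

    Returns a table with one row per ROI pair: roi_a, roi_b, t, p,
    p_adj, significant.
    """
    fc = roi_fc_matrix(cohort, rois)
    return roi_fc_table_test(fc, phenotype, covariates=covariates, q=q)


def roi_fc_table_test(
    fc: pd.DataFrame,
    phenotype: pd.DataFrame,
    covariates: tuple[str, ...] | list[str] = ("age", "education", "mean_fd", "itv"),
    q: float = 0.05,
) -> pd.DataFrame:
    """Group test + BH-FDR on a long-format (subject, roi_a, roi_b, z) table."""
    pheno = phenotype.set_index("subject_id")
    wide = fc.pivot_table(
        index="subject_id", columns=["roi_a", "roi_b"], values="z", sort=False
    )
    wide = wide.loc[pheno.index]
    group = group_vector(pheno.reset_index())
    cov = pheno[list(covariates)].to_numpy(dtype=float) if covariates else None
    t, p, _ = _group_glm(wide.to_numpy(), group, cov)
    p_adj = bh_fdr(p)
    pairs = list(wide.columns)
    return pd.DataFrame(
        {
            "roi_a": [a for a, _ in pairs],
            "roi_b": [b for _, b in pairs],
            "t": t,
            "p": p,
            "p_adj": p_adj,
            "significant": p_adj < q,
        }
    )
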