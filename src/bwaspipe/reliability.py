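"""Time-domain half-split reliability.

Each subject's series is split into first/second temporal halves; the
full link-level stack is recomputed on each half and agreement is
quantified as the Dice coefficient between the thresholded
significant-voxel sets plus the Spearman rank correlation of the two MA
maps over their union. ROIs defined on one half are cross-validated by
re-testing their FC on the other half; both directions are reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from bwaspipe.bwas import run_bwas
from bwaspipe.errors import DataError
from bwaspipe.roi import define_rois, roi_group_fc_test
from bwaspipe.types import ClusterSet, MAMap, ROISet, VoxelCohort


def split_halves(cohort: VoxelCohort) -> tuple[VoxelCohort, VoxelCohort]:
    """First floor(T/2) timepoints versus the remainder, same grid."""
    n_t = cohort.n_timepoints
    if n_t < 4:
        raise DataError("need at least 4 timepoints to split")
    half = n_t // 2
    first = VoxelCohort(
        subject_ids=list(cohort.subject_ids),
        data=cohort.data[:, :, :half].copy(),
        mask=cohort.mask,
        affine=cohort.affine,
    )
    second = VoxelCohort(
        subject_ids=list(cohort.subject_ids),
        data=cohort.data[:, :, half:].copy(),
        mask=cohort.mask,
        affine=cohort.affine,
    )
    return first, second


def dice_coefficient(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|A∩B|/(|A|+|B|) of two voxel-coordinate sets.

    Returns NaN when both sets are empty (undefined, reported as NA).
    """
    set_a = {tuple(c) for c in np.asarray(a).reshape(-1, 3)}
    set_b = {tuple(c) for c in np.asarray(b).reshape(-1, 3)}
    if not set_a and not set_b:
        return float("nan")
    return 2.0 * len(set_a & set_b) / (len(set_a) + len(set_b))


@dataclass
class HalfSplitReport:
    ma_first: MAMap
    ma_second: MAMap
    clusters_first: ClusterSet
    clusters_second: ClusterSet
    n_sig_first: int
    n_sig_second: int
    dice: float
    spearman_rho: float


def half_split_ma(
    cohort: VoxelCohort,
    phenotype: pd.DataFrame,
    **bwas_kwargs,
) -> HalfSplitReport:
    """Recompute the MA stack on each temporal half and compare.

    Dice is computed on the extracted cluster voxel sets; the Spearman
    correlation compares MA values over the union of nonzero-MA voxels
    of the two halves (NaN when that union is empty or has no spread).
    """
    first, second = split_halves(cohort)
    _, ma_a, clusters_a = run_bwas(first, phenotype, **bwas_kwargs)
    _, ma_b, clusters_b = run_bwas(second, phenotype, **bwas_kwargs)
    vox_a = clusters_a.all_voxel_coords()
    vox_b = clusters_b.all_voxel_coords()
    union = (ma_a.counts > 0) | (ma_b.counts > 0)
    if (
        union.sum() >= 2
        and np.ptp(ma_a.counts[union]) > 0
        and np.ptp(ma_b.counts[union]) > 0
    ):
        rho = stats.spearmanr(ma_a.counts[union], ma_b.counts[union]).statistic
    else:
        rho = float("nan")
    return HalfSplitReport(
        ma_first=ma_a,
        ma_second=ma_b,
        clusters_first=clusters_a,
        clusters_second=clusters_b,
        n_sig_first=len(vox_a),
        n_sig_second=len(vox_b),
        dice=dice_coefficient(vox_a, vox_b),
        spearman_rho=float(rho),
    )


def cross_validate_fc(
    rois: ROISet,
    holdout: VoxelCohort,
    phenotype: pd.DataFrame,
    covariates: tuple[str, ...] | list[str] = ("age", "education", "mean_fd", "itv"),
    q: float = 0.05,
) -> pd.DataFrame:
    """Re-test FC of ROIs defined on one half using the other half's data."""
    if len(rois) == 0:
        raise DataError("ROI set from the definition half is empty")
    return roi_group_fc_test(holdout, rois, phenotype, covariates=covariates, q=q)


def half_split_cross_validation(
    cohort: VoxelCohort,
    phenotype: pd.DataFrame,
    atlas_volume: np.ndarray,
    labels: pd.DataFrame,
    roi_min_voxels: int = 20,
    covariates: tuple[str, ...] | list[str] = ("age", "education", "mean_fd", "itv"),
    q: float = 0.05,
    **bwas_kwargs,
) -> dict[str, pd.DataFrame]:
    """Both directions: define ROIs on half A, validate on half B, and
    vice versa. Returns {'a_to_b': ..., 'b_to_a': ...} FC test tables
    (empty table when a definition half yields no ROIs)."""
    first, second = split_halves(cohort)
    out = {}
    for key, (define_half, test_half) in {
        "a_to_b": (first, second),
        "b_to_a": (second, first),
    }.items():
        _, ma, clusters = run_bwas(define_half, phenotype, **bwas_kwargs)
        rois = define_rois(
            clusters.all_voxel_coords(), ma, atlas_volume, labels,
            min_voxels=roi_min_voxels,
        )
        if len(rois) < 2:
            out[key] = pd.DataFrame(
                columns=["roi_a", "roi_b", "t", "p", "p_adj", "significant"]
            )
            continue
        out[key] = cross_validate_fc(
            rois, test_half, phenotype, covariates=covariates, q=q
        )
    return out
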