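"""Link-level brain-wide association core.

All-pairs voxel functional connectivity (Pearson r, Fisher z), a
covariate-adjusted per-link group GLM, Bonferroni family-wise error
control over the link family, the per-voxel measure-of-association (MA)
link-count statistic, and MA-thresholded cluster extraction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from bwaspipe.errors import (
    ConfigurationError,
    DataError,
    DegenerateDesignError,
    DegenerateVoxelError,
    SaturationError,
    UndercountError,
)
from bwaspipe.types import Cluster, ClusterSet, LinkTestTable, MAMap, VoxelCohort

GROUP_CODES = {"CN": 0, "SCD": 1}
DEFAULT_COVARIATES = ("age", "education", "mean_fd", "itv")


def count_links(n_voxels: int, convention: str = "half_squared") -> int:
    """Size of the link-test family used for multiple-comparison correction.

    ``half_squared`` is floor(n^2 / 2); ``pairs`` is the enumerated
    n (n - 1) / 2 unordered-pair count. The enumerated test set is always
    the i < j pairs regardless of convention.
    """
    if n_voxels < 1:
        raise ConfigurationError("n_voxels must be positive")
    if convention == "half_squared":
        return (n_voxels * n_voxels) // 2
    if convention == "pairs":
        return n_voxels * (n_voxels - 1) // 2
    raise ConfigurationError(f"unknown family-size convention: {convention!r}")


def pair_indices(n_voxels: int) -> tuple[np.ndarray, np.ndarray]:
    """Upper-triangle (i < j) voxel index pairs in row-major order."""
    return np.triu_indices(n_voxels, k=1)


def voxel_fc_fisher(cohort: VoxelCohort) -> np.ndarray:
    """Per-subject Fisher-z link values for every voxel pair i < j.

    Returns a (n_subjects, n_pairs) array ordered as
    :func:`pair_indices`. Raises on zero-variance voxels and on |r| = 1
    between distinct voxels (atanh saturation).
    """
    data = cohort.data
    if data.shape[2] < 3:
        raise DataError("need at least 3 timepoints for correlation")
    n_sub, n_vox, n_t = data.shape
    iu, ju = pair_indices(n_vox)
    z = np.empty((n_sub, len(iu)))
    for s in range(n_sub):
        x = data[s]
        sd = x.std(axis=1)
        if np.any(sd == 0):
            bad = np.flatnonzero(sd == 0)
            raise DegenerateVoxelError(
                f"zero-variance voxel series for subject "
                f"{cohort.subject_ids[s]!r}: voxel indices {bad.tolist()}"
            )
        xc = (x - x.mean(axis=1, keepdims=True)) / sd[:, None]
        r = (xc @ xc.T) / n_t
        r_links = np.clip(r[iu, ju], -1.0, 1.0)
        if np.any(np.abs(r_links) >= 1.0):
            raise SaturationError(
                f"|r| = 1 between distinct voxels for subject "
                f"{cohort.subject_ids[s]!r}; Fisher z undefined"
            )
        z[s] = np.arctanh(r_links)
    return z


def group_vector(phenotype: pd.DataFrame) -> np.ndarray:
    """0/1 group coding (CN = 0, SCD = 1) from a phenotype table."""
    groups = phenotype["group"].astype(str)
    unknown = set(groups) - set(GROUP_CODES)
    if unknown:
        raise DataError(f"unknown group labels: {sorted(unknown)}")
    return groups.map(GROUP_CODES).to_numpy(dtype=float)


def _group_glm(
    y: np.ndarray, group: np.ndarray, covariates: np.ndarray | None
) -> tuple[np.ndarray, np.ndarray, int]:
    """Vectorized OLS of each column of ``y`` on intercept + group +
    covariates; returns (t, p, df) for the group coefficient."""
    n = len(group)
    cols = [np.ones(n), group]
    if covariates is not None and covariates.size:
        cols.extend(np.atleast_2d(covariates.T))
    x = np.column_stack(cols)
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise DegenerateDesignError(
            "group-test design is rank deficient (collinear covariates or "
            "a covariate equal to the group indicator)"
        )
    df = n - x.shape[1]
    if df < 1:
        raise DataError("not enough subjects for the covariate count")
    xtx_inv = np.linalg.inv(x.T @ x)
    beta = xtx_inv @ (x.T @ y)
    resid = y - x @ beta
    sigma2 = np.einsum("ij,ij->j", resid, resid) / df
    se = np.sqrt(sigma2 * xtx_inv[1, 1])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta[1] / np.where(se > 0, se, 1.0), 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return t, p, df


def link_group_test(
    link_z: np.ndarray,
    phenotype: pd.DataFrame,
    covariates: tuple[str, ...] | list[str] = DEFAULT_COVARIATES,
    family_convention: str = "half_squared",
    method: str = "glm",
    retain_p: float | None = None,
    alpha: float | None = None,
) -> LinkTestTable:
    """Two-tailed group test on every link's Fisher-z values.

    ``method='glm'`` fits z ~ intercept + group + covariates per link and
    reports the group coefficient's t with df = n - p. ``method='residualize'``
    first residualizes z on the covariates, then applies a pooled-variance
    two-sample t-test to the residuals. With no covariates both reduce to
    the plain two-sample t-test.

    ``retain_p`` restricts the stored records to links with p below the
    cutoff; the family size ``n_links`` still reflects all links.
    """
    link_z = np.asarray(link_z, dtype=float)
    group = group_vector(phenotype)
    n_per = [int((group == g).sum()) for g in (0, 1)]
    if min(n_per) < 2:
        raise DataError(f"each group needs >= 2 subjects, got {n_per}")
    cov = None
    if covariates:
        missing = [c for c in covariates if c not in phenotype.columns]
        if missing:
            raise DataError(f"phenotype table lacks covariates: {missing}")
        cov = phenotype[list(covariates)].to_numpy(dtype=float)
    min_group = min(n_per)
    if cov is not None and min_group < cov.shape[1] + 2:
        raise DataError(
            f"smallest group ({min_group}) must have >= covariates + 2 subjects"
        )
    if method == "glm":
        t, p, _ = _group_glm(link_z, group, cov)
    elif method == "residualize":
        if cov is not None:
            x = np.column_stack([np.ones(len(group)), cov])
            beta, *_ = np.linalg.lstsq(x, link_z, rcond=None)
            link_z = link_z - x @ beta
        t, p, _ = _group_glm(link_z, group, None)
    else:
        raise ConfigurationError(f"unknown test method: {method!r}")

    n_vox = _voxels_from_pairs(link_z.shape[1])
    iu, ju = pair_indices(n_vox)
    n_links = count_links(n_vox, family_convention)
    if retain_p is not None:
        keep = p < retain_p
        iu, ju, t, p = iu[keep], ju[keep], t[keep], p[keep]
    return LinkTestTable(
        i=iu, j=ju, t_stat=t, p_value=p,
        n_links=n_links, n_voxels=n_vox, alpha=alpha,
    )


def _voxels_from_pairs(n_pairs: int) -> int:
    n = int(round((1 + np.sqrt(1 + 8 * n_pairs)) / 2))
    if n * (n - 1) // 2 != n_pairs:
        raise DataError(f"{n_pairs} is not a triangular pair count")
    return n


def fwe_threshold(alpha: float, n_links: int) -> float:
    """Bonferroni per-link uncorrected p cutoff: alpha / n_links."""
    if not 0 < alpha < 1:
        raise ConfigurationError("alpha must lie in (0, 1)")
    if n_links <= 0:
        raise ConfigurationError("n_links must be positive")
    return alpha / n_links


def corrected_p(p_value: np.ndarray, n_links: int) -> np.ndarray:
    """Bonferroni-corrected p: min(1, p * n_links)."""
    return np.minimum(1.0, np.asarray(p_value, dtype=float) * n_links)


def compute_ma(
    links: LinkTestTable,
    alpha: float,
    n_links: int | None = None,
    mask: np.ndarray | None = None,
    affine: np.ndarray | None = None,
    retain_p: float | None = None,
) -> MAMap:
    """Per-voxel count of FWE-significant incident links.

    MA(i) = #{links (i, j) with p < alpha / n_links}. The sum of MA over
    voxels equals twice the significant-link count.
    """
    family = links.n_links if n_links is None else n_links
    cutoff = fwe_threshold(alpha, family)
    if retain_p is not None and retain_p < cutoff:
        raise UndercountError(
            f"retention cutoff {retain_p} is below the FWE cutoff {cutoff}; "
            "significant links may be missing"
        )
    sig = links.p_value < cutoff
    counts = (
        np.bincount(links.i[sig], minlength=links.n_voxels)
        + np.bincount(links.j[sig], minlength=links.n_voxels)
    )
    if mask is None:
        mask = np.ones((links.n_voxels, 1, 1), dtype=bool)
    if affine is None:
        affine = np.eye(4)
    return MAMap(counts=counts, mask=mask, affine=affine, alpha=alpha)


def extract_clusters(
    ma: MAMap,
    ma_min: int = 40,
    min_cluster_voxels: int = 20,
    connectivity: int = 26,
) -> ClusterSet:
    """Connected components of voxels with MA strictly above ``ma_min``.

    Components smaller than ``min_cluster_voxels`` are dropped. The peak
    voxel is the member with the highest MA (ties broken by lowest linear
    index); its world coordinate comes from the affine.
    """
    if ma_min < 0 or min_cluster_voxels < 0:
        raise ConfigurationError("thresholds must be nonnegative")
    if connectivity == 26:
        structure = np.ones((3, 3, 3), dtype=bool)
    elif connectivity == 6:
        structure = ndimage.generate_binary_structure(3, 1)
    else:
        raise ConfigurationError("connectivity must be 6 or 26")
    vol = ma.to_volume()
    above = vol > ma_min
    labeled, n_comp = ndimage.label(above, structure=structure)
    clusters: list[Cluster] = []
    for comp in range(1, n_comp + 1):
        coords = np.argwhere(labeled == comp)
        if len(coords) < min_cluster_voxels:
            continue
        values = vol[tuple(coords.T)]
        peak_local = int(np.argmax(values))  # argmax -> first max, and
        # argwhere is ascending-linear-index order, so ties pick lowest index
        peak_coord = coords[peak_local]
        hom = np.append(peak_coord, 1.0)
        peak_world = (ma.affine @ hom)[:3]
        clusters.append(
            Cluster(
                cluster_id=len(clusters) + 1,
                voxel_coords=coords,
                peak_ma=int(values[peak_local]),
                peak_coord=peak_coord,
                peak_world=peak_world,
            )
        )
    return ClusterSet(clusters=clusters)


def run_bwas(
    cohort: VoxelCohort,
    phenotype: pd.DataFrame,
    alpha: float = 3.33e-2,
    covariates: tuple[str, ...] | list[str] = DEFAULT_COVARIATES,
    family_convention: str = "half_squared",
    ma_min: int = 40,
    min_cluster_voxels: int = 20,
    connectivity: int = 26,
    method: str = "glm",
) -> tuple[LinkTestTable, MAMap, ClusterSet]:
    """Full link-level stack: FC -> group test -> MA -> clusters."""
    link_z = voxel_fc_fisher(cohort)
    links = link_group_test(
        link_z, phenotype, covariates=covariates,
        family_convention=family_convention, method=method, alpha=alpha,
    )
    ma = compute_ma(links, alpha, mask=cohort.mask, affine=cohort.affine)
    clusters = extract_clusters(ma, ma_min, min_cluster_voxels, connectivity)
    return links, ma, clusters
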