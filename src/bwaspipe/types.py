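"""Core data containers shared across pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from bwaspipe.errors import AlignmentError, DataError


@dataclass
class VoxelCohort:
    """Per-subject masked voxel-by-time matrices on a shared grid.

    Voxel ordering is the ascending linear (C-order) index of the in-mask
    voxels, identical for every subject. ``affine`` maps voxel indices to
    world coordinates.
    """

    subject_ids: list[str]
    data: np.ndarray  # (n_subjects, n_voxels, n_timepoints)
    mask: np.ndarray  # 3D bool
    affine: np.ndarray  # (4, 4)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise DataError("cohort data must be (subjects, voxels, timepoints)")
        if len(self.subject_ids) != self.data.shape[0]:
            raise DataError("subject id count does not match data")
        if self.data.shape[1] != int(self.mask.sum()):
            raise AlignmentError(
                f"cohort has {self.data.shape[1]} voxels but mask has "
                f"{int(self.mask.sum())}"
            )

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.data.shape[1]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[2]

    @property
    def voxel_coords(self) -> np.ndarray:
        """(n_voxels, 3) integer grid coordinates, mask order."""
        return np.argwhere(self.mask)

    def world_coords(self, coords: np.ndarray) -> np.ndarray:
        """Map (k, 3) voxel coordinates to world space via the affine."""
        coords = np.atleast_2d(coords)
        hom = np.column_stack([coords, np.ones(len(coords))])
        return (self.affine @ hom.T).T[:, :3]


@dataclass
class LinkTestTable:
    """Link-level group-test records over voxel pairs i < j.

    ``n_links`` is the family size used for multiple-comparison correction;
    it always reflects the full link family even when the stored records
    are restricted to p-values below a retention cutoff.
    """

    i: np.ndarray
    j: np.ndarray
    t_stat: np.ndarray
    p_value: np.ndarray
    n_links: int
    n_voxels: int
    alpha: float | None = None

    def __post_init__(self) -> None:
        self.i = np.asarray(self.i, dtype=np.int64)
        self.j = np.asarray(self.j, dtype=np.int64)
        if np.any(self.i >= self.j):
            raise DataError("link records must satisfy i < j")
        p = np.asarray(self.p_value, dtype=float)
        if np.any((p < 0) | (p > 1)):
            raise DataError("p-values must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.i)


@dataclass
class MAMap:
    """Per-voxel count of significant incident links, on the cohort grid."""

    counts: np.ndarray  # (n_voxels,) nonnegative ints, mask order
    mask: np.ndarray
    affine: np.ndarray
    alpha: float

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if np.any(self.counts < 0):
            raise DataError("MA counts must be nonnegative")
        if np.any(self.counts > int(self.mask.sum()) - 1):
            raise DataError("MA count exceeds n_voxels - 1")

    def to_volume(self) -> np.ndarray:
        vol = np.zeros(self.mask.shape, dtype=np.int64)
        vol[self.mask] = self.counts
        return vol


@dataclass
class Cluster:
    """Connected component of above-threshold MA voxels."""

    cluster_id: int
    voxel_coords: np.ndarray  # (k, 3) grid coordinates
    peak_ma: int
    peak_coord: np.ndarray  # (3,) grid coordinate of the peak voxel
    peak_world: np.ndarray  # (3,) world coordinate of the peak voxel

    @property
    def size(self) -> int:
        return len(self.voxel_coords)


@dataclass
class ClusterSet:
    clusters: list[Cluster] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.clusters)

    def __iter__(self):
        return iter(self.clusters)

    def all_voxel_coords(self) -> np.ndarray:
        if not self.clusters:
            return np.empty((0, 3), dtype=np.int64)
        return np.vstack([c.voxel_coords for c in self.clusters])


@dataclass
class ROI:
    """Atlas-region-anchored ROI built from significant voxels."""

    region_id: int
    name: str
    voxel_coords: np.ndarray  # (k, 3) significant voxels carrying this label
    peak_ma: int
    peak_coord: np.ndarray
    peak_world: np.ndarray

    @property
    def n_voxels(self) -> int:
        return len(self.voxel_coords)


@dataclass
class ROISet:
    rois: list[ROI] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.rois)

    def __iter__(self):
        return iter(self.rois)

    @property
    def names(self) -> list[str]:
        return [r.name for r in self.rois]
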