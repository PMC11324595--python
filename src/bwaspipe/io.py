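"""Readers and writers for the pipeline's on-disk formats.

NIfTI (4D data, mask, atlas, MA map) via nibabel; motion traces as
6-column whitespace text; labels as TSV; phenotype as CSV; configs and
domain manifests as YAML.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from bwaspipe.errors import AlignmentError, DataError, FormatError
from bwaspipe.types import MAMap, VoxelCohort


def write_nifti(path: Path | str, data: np.ndarray, affine: np.ndarray) -> None:
    nib.save(nib.Nifti1Image(np.asarray(data), np.asarray(affine)), str(path))


def read_nifti(path: Path | str) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.get_fdata()), np.asarray(img.affine)


def write_cohort(
    out_dir: Path | str, cohort: VoxelCohort, motion: dict[str, np.ndarray] | None = None
) -> None:
    """One 4D NIfTI per subject plus mask.nii.gz and optional motion text."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_nifti(out / "mask.nii.gz", cohort.mask.astype(np.uint8), cohort.affine)
    for s, sid in enumerate(cohort.subject_ids):
        vol = np.zeros((*cohort.mask.shape, cohort.n_timepoints), dtype=np.float32)
        vol[cohort.mask] = cohort.data[s]
        write_nifti(out / f"{sid}_bold.nii.gz", vol, cohort.affine)
        if motion is not None and sid in motion:
            write_motion(out / f"{sid}_motion.txt", motion[sid])


def read_cohort(cohort_dir: Path | str, mask_path: Path | str | None = None) -> VoxelCohort:
    """Load all ``*_bold.nii.gz`` volumes under a directory into a cohort.

    Every subject volume must share the mask's grid shape and affine;
    voxel ordering is the ascending linear index of the in-mask voxels.
    """
    cohort_dir = Path(cohort_dir)
    if mask_path is None:
        mask_path = cohort_dir / "mask.nii.gz"
    mask_data, affine = read_nifti(mask_path)
    mask = mask_data > 0
    if mask.sum() == 0:
        raise DataError(f"mask {mask_path} contains no voxels")
    paths = sorted(cohort_dir.glob("*_bold.nii*"))
    if not paths:
        raise DataError(f"no *_bold.nii* volumes under {cohort_dir}")
    subject_ids, stacks = [], []
    for p in paths:
        sid = p.name.split("_bold")[0]
        vol, vol_affine = read_nifti(p)
        if vol.shape[:3] != mask.shape or not np.allclose(vol_affine, affine):
            raise AlignmentError(
                f"subject {sid!r}: volume grid/affine does not match the mask"
            )
        if vol.ndim != 4:
            raise FormatError(f"subject {sid!r}: expected a 4D volume")
        subject_ids.append(sid)
        stacks.append(vol[mask])
    lengths = {s.shape[1] for s in stacks}
    if len(lengths) != 1:
        raise DataError(f"subjects differ in timepoint count: {sorted(lengths)}")
    return VoxelCohort(
        subject_ids=subject_ids,
        data=np.stack(stacks),
        mask=mask,
        affine=affine,
    )


def write_motion(path: Path | str, motion: np.ndarray) -> None:
    np.savetxt(str(path), np.asarray(motion, dtype=float), fmt="%.8f")


def read_motion(path: Path | str) -> np.ndarray:
    motion = np.loadtxt(str(path))
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise FormatError(
            f"motion file {path} must have 6 columns, got shape {motion.shape}"
        )
    return motion


def write_labels(path: Path | str, labels: pd.DataFrame) -> None:
    labels.to_csv(path, sep="\t", index=False)


def read_labels(path: Path | str) -> pd.DataFrame:
    labels = pd.read_csv(path, sep="\t")
    if not {"region_id", "name"} <= set(labels.columns):
        raise FormatError(f"label table {path} needs columns region_id, name")
    return labels


def write_phenotype(path: Path | str, phenotype: pd.DataFrame) -> None:
    phenotype.to_csv(path, index=False)


def read_phenotype(path: Path | str) -> pd.DataFrame:
    pheno = pd.read_csv(path)
    required = {"subject_id", "group"}
    if not required <= set(pheno.columns):
        raise FormatError(f"phenotype table {path} needs columns {sorted(required)}")
    return pheno


def write_ma_map(path: Path | str, ma: MAMap) -> None:
    write_nifti(path, ma.to_volume().astype(np.int32), ma.affine)


def read_yaml(path: Path | str) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def write_yaml(path: Path | str, payload: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)
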