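"""Pipeline configuration.

Every numeric constant the analysis uses (link-test alpha, MA and
cluster-size thresholds, ROI voxel minimum, FDR q, bootstrap count)
lives here and nowhere else; stage code receives them as arguments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from bwaspipe.errors import ConfigurationError


@dataclass
class PrepSettings:
    tr_seconds: float = 2.0
    low_hz: float = 0.01
    high_hz: float = 0.1
    fwhm_mm: float = 8.0
    voxel_size_mm: float = 4.0
    head_radius_mm: float = 50.0


@dataclass
class BwasSettings:
    alpha: float = 3.33e-2
    family_convention: str = "half_squared"  # or "pairs"
    ma_min: int = 40
    min_cluster_voxels: int = 20
    connectivity: int = 26
    roi_min_voxels: int = 20
    covariates: tuple[str, ...] = ("age", "education", "mean_fd", "itv")
    method: str = "glm"  # or "residualize"


@dataclass
class RoiSettings:
    q: float = 0.05


@dataclass
class CognitionSettings:
    n_boot: int = 10_000
    seed: int = 0
    covariates: tuple[str, ...] = ("age", "gender", "education")
    group: str = "SCD"


@dataclass
class PipelineConfig:
    cohort_dir: Path
    phenotype_path: Path
    atlas_path: Path | None = None
    labels_path: Path | None = None
    mask_path: Path | None = None
    motion_dir: Path | None = None
    manifest_path: Path | None = None
    out_dir: Path = Path("bwas_out")
    prep: PrepSettings = field(default_factory=PrepSettings)
    bwas: BwasSettings = field(default_factory=BwasSettings)
    roi: RoiSettings = field(default_factory=RoiSettings)
    cognition: CognitionSettings = field(default_factory=CognitionSettings)
    run_prep: bool = False
    run_reliability: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.bwas.alpha < 1:
            raise ConfigurationError("alpha must lie in (0, 1)")
        if not 0 < self.roi.q < 1:
            raise ConfigurationError("q must lie in (0, 1)")
        for name, value in (
            ("ma_min", self.bwas.ma_min),
            ("min_cluster_voxels", self.bwas.min_cluster_voxels),
            ("roi_min_voxels", self.bwas.roi_min_voxels),
            ("n_boot", self.cognition.n_boot),
        ):
            if value <= 0:
                raise ConfigurationError(f"{name} must be positive")


def pipeline_config_from_dict(payload: dict) -> PipelineConfig:
    """Build a PipelineConfig from a (YAML-loaded) nested mapping."""
    payload = dict(payload)
    sections = {}
    for key, cls in (
        ("prep", PrepSettings),
        ("bwas", BwasSettings),
        ("roi", RoiSettings),
        ("cognition", CognitionSettings),
    ):
        spec = payload.pop(key, {}) or {}
        if "covariates" in spec:
            spec["covariates"] = tuple(spec["covariates"])
        sections[key] = cls(**spec)
    for key in (
        "cohort_dir", "phenotype_path", "atlas_path", "labels_path",
        "mask_path", "motion_dir", "manifest_path", "out_dir",
    ):
        if payload.get(key) is not None:
            payload[key] = Path(payload[key])
    return PipelineConfig(**payload, **sections)
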