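"""Synthetic two-group fMRI-like cohorts with known ground truth.

Each declared cluster carries a latent band-limited Gaussian time course.
Between-cluster correlations are induced by mixing independent latents
through the Cholesky factor of a per-group target correlation matrix,
with the targets analytically inflated so that the *expected* Pearson
correlation between cluster-mean signals (latent plus averaged voxel
noise) equals the declared group value. Cognition domain scores are
slope x subject-level circuit FC (Fisher z) plus Gaussian noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from bwaspipe.errors import ConfigurationError
from bwaspipe.prep import bandpass, fd_power
from bwaspipe.types import VoxelCohort

DOMAINS = ("EM", "EF", "VF", "IPS")

DEFAULT_COVARIATE_DISTRIBUTIONS: dict[str, dict[str, float]] = {
    "age": {"loc": 64.0, "scale": 7.0},
    "education": {"loc": 12.0, "scale": 2.6},
    "itv": {"loc": 1416.0, "scale": 105.0, "loc_scd": 1365.0},
    "gender": {"p_male": 0.42, "p_male_scd": 0.21},
}


@dataclass
class CircuitEffect:
    """Declared correlation between two clusters, per group."""

    cluster_a: str
    cluster_b: str
    r_cn: float
    r_scd: float


@dataclass
class CognitionCoupling:
    """Linear coupling of a cognitive domain to a circuit's Fisher-z FC."""

    cluster_a: str
    cluster_b: str
    domain: str
    slope: float
    noise_sd: float


@dataclass
class SimulationConfig:
    grid_shape: tuple[int, int, int]
    n_timepoints: int
    n_subjects_per_group: tuple[int, int]  # (n_cn, n_scd)
    signal_clusters: dict[str, np.ndarray]  # id -> (k, 3) grid coordinates
    circuit_effects: list[CircuitEffect] = field(default_factory=list)
    cognition_couplings: list[CognitionCoupling] = field(default_factory=list)
    tr_seconds: float = 2.0
    noise_sd: float = 0.5
    noise_ar1: float = 0.0
    covariate_distributions: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            k: dict(v) for k, v in DEFAULT_COVARIATE_DISTRIBUTIONS.items()
        }
    )
    motion_step_mm: float = 0.02
    motion_step_rad: float = 2e-4
    seed: int = 0

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(s) for s in self.grid_shape)
        if len(self.grid_shape) != 3 or any(s < 1 for s in self.grid_shape):
            raise ConfigurationError("grid_shape must be 3 positive integers")
        if self.n_timepoints < 4:
            raise ConfigurationError("n_timepoints must be >= 4")
        if any(n < 1 for n in self.n_subjects_per_group):
            raise ConfigurationError("both group sizes must be positive")
        if not 0 <= self.noise_ar1 < 1:
            raise ConfigurationError("noise_ar1 must lie in [0, 1)")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be nonnegative")
        self.signal_clusters = {
            str(k): np.asarray(v, dtype=np.int64).reshape(-1, 3)
            for k, v in self.signal_clusters.items()
        }
        seen: set[tuple[int, int, int]] = set()
        total = 0
        for name, coords in self.signal_clusters.items():
            for c in map(tuple, coords):
                if any(ci < 0 or ci >= s for ci, s in zip(c, self.grid_shape)):
                    raise ConfigurationError(
                        f"cluster {name!r} voxel {c} outside grid {self.grid_shape}"
                    )
                if c in seen:
                    raise ConfigurationError(
                        f"clusters overlap at voxel {c} (cluster {name!r})"
                    )
                seen.add(c)
            total += len(coords)
        if total > int(np.prod(self.grid_shape)):
            raise ConfigurationError("clusters exceed grid volume")
        for eff in self.circuit_effects:
            for r in (eff.r_cn, eff.r_scd):
                if not -1 < r < 1:
                    raise ConfigurationError(
                        f"circuit correlation {r} must lie in (-1, 1)"
                    )
            for name in (eff.cluster_a, eff.cluster_b):
                if name not in self.signal_clusters:
                    raise ConfigurationError(f"unknown cluster {name!r}")
        for cpl in self.cognition_couplings:
            if cpl.domain not in DOMAINS:
                raise ConfigurationError(f"unknown domain {cpl.domain!r}")
            for name in (cpl.cluster_a, cpl.cluster_b):
                if name not in self.signal_clusters:
                    raise ConfigurationError(f"unknown cluster {name!r}")


@dataclass
class GroundTruth:
    affected_voxels: np.ndarray  # (k, 3) coordinates, union over circuits
    affected_circuits: list[tuple[str, str]]
    cognition_slopes: dict[tuple[str, str, str], float]
    circuit_fc_z: pd.DataFrame  # per-subject realized circuit Fisher z


def _latent_correlation_targets(
    config: SimulationConfig, group: str
) -> np.ndarray:
    """Per-group latent correlation matrix, inflated to cancel the
    attenuation from averaged voxel noise in the cluster-mean signals."""
    names = list(config.signal_clusters)
    idx = {n: k for k, n in enumerate(names)}
    r_mat = np.eye(len(names))
    var_noise = config.noise_sd**2
    for eff in config.circuit_effects:
        r = eff.r_cn if group == "CN" else eff.r_scd
        m_a = len(config.signal_clusters[eff.cluster_a])
        m_b = len(config.signal_clusters[eff.cluster_b])
        inflate = np.sqrt((1 + var_noise / m_a) * (1 + var_noise / m_b))
        r_target = r * inflate
        if abs(r_target) >= 1:
            raise ConfigurationError(
                f"declared correlation {r} for circuit "
                f"({eff.cluster_a}, {eff.cluster_b}) is unattainable after "
                f"noise-attenuation correction ({r_target:.3f})"
            )
        a, b = idx[eff.cluster_a], idx[eff.cluster_b]
        r_mat[a, b] = r_mat[b, a] = r_target
    try:
        np.linalg.cholesky(r_mat)
    except np.linalg.LinAlgError as exc:
        raise ConfigurationError(
            "circuit correlation targets are jointly infeasible "
            "(not positive definite)"
        ) from exc
    return r_mat


def _band_limited_latents(
    rng: np.random.Generator, n_series: int, n_t: int, tr: float
) -> np.ndarray:
    """Independent unit-variance band-limited (0.01-0.1 Hz) series."""
    white = rng.standard_normal((n_series, n_t))
    high = min(0.1, 0.45 / tr)  # stay under Nyquist on coarse TRs
    filtered = bandpass(white, tr, 0.01, high)
    sd = filtered.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (filtered - filtered.mean(axis=1, keepdims=True)) / sd


def _ar1_noise(
    rng: np.random.Generator, shape: tuple[int, ...], sd: float, phi: float
) -> np.ndarray:
    """AR(1) noise with marginal standard deviation ``sd``."""
    if sd == 0:
        return np.zeros(shape)
    innov_sd = sd * np.sqrt(1 - phi**2)
    eps = rng.standard_normal(shape) * innov_sd
    if phi == 0:
        return eps * (sd / innov_sd) if innov_sd else eps
    out = np.empty(shape)
    out[..., 0] = rng.standard_normal(shape[:-1]) * sd
    for t in range(1, shape[-1]):
        out[..., t] = phi * out[..., t - 1] + eps[..., t]
    return out


def _simulate_motion(
    rng: np.random.Generator, n_t: int, step_mm: float, step_rad: float
) -> np.ndarray:
    steps = np.column_stack(
        [
            rng.standard_normal((n_t, 3)) * step_mm,
            rng.standard_normal((n_t, 3)) * step_rad,
        ]
    )
    steps[0] = 0.0
    return np.cumsum(steps, axis=0)


def _draw_covariates(
    rng: np.random.Generator, dists: dict[str, dict[str, float]], groups: list[str]
) -> pd.DataFrame:
    n = len(groups)
    is_scd = np.array([g == "SCD" for g in groups])
    out: dict[str, np.ndarray] = {}
    for name in ("age", "education", "itv"):
        d = dists.get(name, DEFAULT_COVARIATE_DISTRIBUTIONS[name])
        loc = np.where(is_scd, d.get("loc_scd", d["loc"]), d["loc"])
        out[name] = rng.normal(loc, d["scale"], size=n)
    g = dists.get("gender", DEFAULT_COVARIATE_DISTRIBUTIONS["gender"])
    p_male = np.where(is_scd, g.get("p_male_scd", g["p_male"]), g["p_male"])
    out["gender"] = (rng.random(n) < p_male).astype(int)
    return pd.DataFrame(out)


def generate_cohort(
    config: SimulationConfig,
) -> tuple[VoxelCohort, pd.DataFrame, dict[str, np.ndarray], GroundTruth]:
    """Generate a two-group cohort with declared FC structure.

    Returns the cohort, its phenotype table, per-subject motion traces,
    and the generating ground truth. Fully reproducible from the config
    seed.
    """
    rng = np.random.default_rng(config.seed)
    n_cn, n_scd = config.n_subjects_per_group
    groups = ["CN"] * n_cn + ["SCD"] * n_scd
    subject_ids = [f"sub-{k + 1:03d}" for k in range(len(groups))]
    names = list(config.signal_clusters)
    n_clusters = len(names)
    grid = config.grid_shape
    mask = np.ones(grid, dtype=bool)
    n_vox = int(np.prod(grid))
    n_t = config.n_timepoints

    chol = {
        g: np.linalg.cholesky(_latent_correlation_targets(config, g))
        for g in ("CN", "SCD")
    }
    cluster_flat = {
        name: np.ravel_multi_index(coords.T, grid)
        for name, coords in config.signal_clusters.items()
    }

    data = np.empty((len(groups), n_vox, n_t))
    circuit_pairs = sorted(
        {tuple(sorted((c.cluster_a, c.cluster_b))) for c in config.circuit_effects}
        | {
            tuple(sorted((c.cluster_a, c.cluster_b)))
            for c in config.cognition_couplings
        }
    )
    fc_rows = []
    for s, group in enumerate(groups):
        latents = _band_limited_latents(rng, n_clusters, n_t, config.tr_seconds)
        mixed = chol[group] @ latents if n_clusters else latents
        noise = _ar1_noise(rng, (n_vox, n_t), config.noise_sd, config.noise_ar1)
        sub = noise
        for k, name in enumerate(names):
            sub[cluster_flat[name]] += mixed[k]
        data[s] = sub
        row: dict[str, float] = {}
        for a, b in circuit_pairs:
            sa = sub[cluster_flat[a]].mean(axis=0)
            sb = sub[cluster_flat[b]].mean(axis=0)
            r = float(np.corrcoef(sa, sb)[0, 1])
            row[f"{a}|{b}"] = float(np.arctanh(np.clip(r, -0.999999, 0.999999)))
        fc_rows.append(row)
    circuit_fc_z = pd.DataFrame(fc_rows, index=subject_ids)

    motion = {
        sid: _simulate_motion(
            rng, n_t, config.motion_step_mm, config.motion_step_rad
        )
        for sid in subject_ids
    }
    mean_fd = [fd_power(motion[sid])[1] for sid in subject_ids]

    pheno = _draw_covariates(rng, config.covariate_distributions, groups)
    pheno.insert(0, "subject_id", subject_ids)
    pheno.insert(1, "group", groups)
    pheno["mean_fd"] = mean_fd

    slopes: dict[tuple[str, str, str], float] = {}
    for domain in DOMAINS:
        couplings = [c for c in config.cognition_couplings if c.domain == domain]
        score = np.zeros(len(groups))
        if couplings:
            for cpl in couplings:
                a, b = sorted((cpl.cluster_a, cpl.cluster_b))
                score += cpl.slope * circuit_fc_z[f"{a}|{b}"].to_numpy()
                score += rng.normal(0.0, cpl.noise_sd, size=len(groups))
                slopes[(a, b, domain)] = cpl.slope
        else:
            score = rng.normal(0.0, 1.0, size=len(groups))
        pheno[f"{domain}_test1"] = score

    affected = sorted(
        {
            tuple(sorted((eff.cluster_a, eff.cluster_b)))
            for eff in config.circuit_effects
            if eff.r_cn != eff.r_scd
        }
    )
    affected_names = sorted({n for pair in affected for n in pair})
    if affected_names:
        affected_voxels = np.vstack(
            [config.signal_clusters[n] for n in affected_names]
        )
    else:
        affected_voxels = np.empty((0, 3), dtype=np.int64)
    truth = GroundTruth(
        affected_voxels=affected_voxels,
        affected_circuits=[tuple(p) for p in affected],
        cognition_slopes=slopes,
        circuit_fc_z=circuit_fc_z,
    )
    cohort = VoxelCohort(
        subject_ids=subject_ids, data=data, mask=mask, affine=np.eye(4)
    )
    return cohort, pheno, motion, truth


def generate_toy_atlas(
    grid_shape: tuple[int, int, int],
    n_regions: int,
    seed: int = 0,
    mask: np.ndarray | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Tile the in-mask voxels into ``n_regions`` contiguous labeled regions.

    Consecutive runs of ascending linear indices form each region, which
    keeps regions contiguous on a full-grid mask. Returns the integer
    label volume (0 outside the mask) and a label table (region_id, name).
    """
    del seed  # tiling is deterministic; kept for interface stability
    grid_shape = tuple(int(s) for s in grid_shape)
    if mask is None:
        mask = np.ones(grid_shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    n_in = int(mask.sum())
    if n_regions < 1:
        raise ConfigurationError("n_regions must be >= 1")
    if n_regions > n_in:
        raise ConfigurationError(
            f"n_regions={n_regions} exceeds in-mask voxel count {n_in}"
        )
    flat_idx = np.flatnonzero(mask)
    bounds = np.linspace(0, n_in, n_regions + 1).astype(int)
    labels = np.zeros(int(np.prod(grid_shape)), dtype=np.int32)
    for rid in range(n_regions):
        labels[flat_idx[bounds[rid] : bounds[rid + 1]]] = rid + 1
    volume = labels.reshape(grid_shape)
    table = pd.DataFrame(
        {
            "region_id": np.arange(1, n_regions + 1),
            "name": [f"Region_{k:03d}" for k in range(1, n_regions + 1)],
        }
    )
    return volume, table


def block_cluster(corner: tuple[int, int, int], shape: tuple[int, int, int]) -> np.ndarray:
    """Convenience: the (k, 3) coordinates of an axis-aligned block."""
    ranges = [np.arange(c, c + s) for c, s in zip(corner, shape)]
    return np.stack(np.meshgrid(*ranges, indexing="ij"), axis=-1).reshape(-1, 3)
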