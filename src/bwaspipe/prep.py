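"""Time-series preprocessing: nuisance regression, filtering, smoothing,
framewise displacement, and intracranial volume.

The fixed stage order applied by :func:`prep_subject` is nuisance
regression, then spatial smoothing, then band-pass filtering.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from bwaspipe.errors import (
    ConfigurationError,
    DataError,
    DegenerateDesignError,
    FormatError,
)

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def friston24(motion: np.ndarray) -> np.ndarray:
    """Expand 6 rigid-body motion parameters into the 24-regressor model.

    Columns are, for each base parameter p: [p, p^2, p_lag1, p_lag1^2];
    the lag-1 rows are zero-padded at t=0.

    Parameters
    ----------
    motion : (T, 6) array
        Three translations (mm) and three rotations (radians) per timepoint.

    Returns
    -------
    (T, 24) array
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise FormatError(f"motion must have 6 columns, got shape {motion.shape}")
    if motion.shape[0] < 2:
        raise DataError("need at least 2 timepoints")
    lag = np.zeros_like(motion)
    lag[1:] = motion[:-1]
    return np.hstack([motion, motion**2, lag, lag**2])


def fd_power(motion: np.ndarray, head_radius_mm: float = 50.0):
    """Framewise displacement: backward-difference sum with rotations
    converted to arc length on a sphere of ``head_radius_mm``.

    FD_t = sum |d translation| + r * sum |d rotation|, with FD_0 = 0.

    Returns
    -------
    fd : (T,) array
    mean_fd : float
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise FormatError(f"motion must have 6 columns, got shape {motion.shape}")
    if motion.shape[0] < 2:
        raise DataError("need at least 2 timepoints")
    if not np.all(np.isfinite(motion)):
        raise DataError("motion parameters contain non-finite values")
    diff = np.diff(motion, axis=0)
    fd = np.zeros(motion.shape[0])
    fd[1:] = np.abs(diff[:, :3]).sum(axis=1) + head_radius_mm * np.abs(
        diff[:, 3:]
    ).sum(axis=1)
    return fd, float(fd.mean())


def build_nuisance_design(
    motion: np.ndarray,
    wm_signal: np.ndarray | None = None,
    csf_signal: np.ndarray | None = None,
) -> np.ndarray:
    """Assemble the nuisance design: Friston-24, WM/CSF means, linear
    trend, and an intercept column (last)."""
    cols = [friston24(motion)]
    n_t = cols[0].shape[0]
    for name, sig in (("wm", wm_signal), ("csf", csf_signal)):
        if sig is not None:
            sig = np.asarray(sig, dtype=float)
            if sig.shape != (n_t,):
                raise FormatError(f"{name} signal length does not match motion")
            cols.append(sig[:, None])
    trend = np.linspace(-1.0, 1.0, n_t)
    cols.append(trend[:, None])
    cols.append(np.ones((n_t, 1)))
    return np.hstack(cols)


def regress_nuisance(series: np.ndarray, design: np.ndarray) -> np.ndarray:
    """Least-squares residuals of each voxel series on the design columns.

    Constant (all-equal) design columns beyond the first such column are
    dropped before the rank check, since the Friston expansion of a still
    trace is legitimately all zeros.
    """
    series = np.asarray(series, dtype=float)
    design = np.asarray(design, dtype=float)
    if series.shape[-1] != design.shape[0]:
        raise DataError(
            f"series has {series.shape[-1]} timepoints but design has "
            f"{design.shape[0]} rows"
        )
    keep = _nonredundant_columns(design)
    reduced = design[:, keep]
    rank = np.linalg.matrix_rank(reduced)
    if rank < reduced.shape[1]:
        bad = _collinear_columns(reduced)
        raise DegenerateDesignError(
            f"design is rank deficient (rank {rank} < {reduced.shape[1]}); "
            f"collinear columns (of retained set): {bad}"
        )
    beta, *_ = np.linalg.lstsq(reduced, series.T, rcond=None)
    return series - (reduced @ beta).T


def _nonredundant_columns(design: np.ndarray) -> np.ndarray:
    """Indices of columns to keep: drop exact-duplicate constant columns."""
    keep = []
    seen_const = False
    for k in range(design.shape[1]):
        col = design[:, k]
        if np.ptp(col) == 0:
            if col[0] == 0 or seen_const:
                continue
            seen_const = True
        keep.append(k)
    return np.asarray(keep, dtype=int)


def _collinear_columns(design: np.ndarray) -> list[int]:
    cols = []
    rank = 0
    basis = np.empty((design.shape[0], 0))
    for k in range(design.shape[1]):
        trial = np.column_stack([basis, design[:, k]])
        r = np.linalg.matrix_rank(trial)
        if r == rank:
            cols.append(k)
        else:
            basis, rank = trial, r
    return cols


def bandpass(
    series: np.ndarray,
    tr_seconds: float,
    low_hz: float = 0.01,
    high_hz: float = 0.1,
) -> np.ndarray:
    """Band-pass filter along the last axis by hard frequency-domain
    masking. Removes the DC component; retains bins with
    low_hz <= f <= high_hz.
    """
    if tr_seconds <= 0:
        raise ConfigurationError("tr_seconds must be positive")
    nyquist = 1.0 / (2.0 * tr_seconds)
    if high_hz >= nyquist:
        raise ConfigurationError(
            f"high_hz={high_hz} must be below the Nyquist frequency {nyquist}"
        )
    if not 0 <= low_hz < high_hz:
        raise ConfigurationError("need 0 <= low_hz < high_hz")
    series = np.asarray(series, dtype=float)
    n_t = series.shape[-1]
    freqs = np.fft.rfftfreq(n_t, d=tr_seconds)
    keep = (freqs >= low_hz) & (freqs <= high_hz) & (freqs > 0)
    spec = np.fft.rfft(series, axis=-1)
    spec[..., ~keep] = 0
    return np.fft.irfft(spec, n=n_t, axis=-1)


def gaussian_smooth(
    volumes: np.ndarray,
    fwhm_mm: float,
    voxel_size_mm: float | tuple[float, float, float] = 1.0,
) -> np.ndarray:
    """3D Gaussian smoothing of each volume of a 4D (x, y, z, t) series.

    sigma per axis = fwhm / (2 sqrt(2 ln 2)) in voxel units; boundary
    handling is reflection. fwhm 0 is the identity.
    """
    if fwhm_mm < 0:
        raise ConfigurationError("fwhm_mm must be nonnegative")
    volumes = np.asarray(volumes, dtype=float)
    if fwhm_mm == 0:
        return volumes.copy()
    vs = np.broadcast_to(np.asarray(voxel_size_mm, dtype=float), (3,))
    sigma_vox = fwhm_mm * FWHM_TO_SIGMA / vs
    if volumes.ndim == 3:
        return ndimage.gaussian_filter(volumes, sigma=sigma_vox, mode="reflect")
    if volumes.ndim != 4:
        raise DataError("expected a 3D volume or 4D (x, y, z, t) series")
    out = np.empty_like(volumes)
    for t in range(volumes.shape[-1]):
        out[..., t] = ndimage.gaussian_filter(
            volumes[..., t], sigma=sigma_vox, mode="reflect"
        )
    return out


def intracranial_volume(
    gm_volume_ml: float, wm_volume_ml: float, csf_volume_ml: float
) -> float:
    """Global intracranial volume: sum of GM, WM, and CSF volumes (ml)."""
    vols = (gm_volume_ml, wm_volume_ml, csf_volume_ml)
    if any(v < 0 for v in vols):
        raise DataError("tissue volumes must be nonnegative")
    return float(sum(vols))


def prep_subject(
    volumes: np.ndarray,
    motion: np.ndarray,
    mask: np.ndarray,
    tr_seconds: float,
    fwhm_mm: float = 0.0,
    voxel_size_mm: float | tuple[float, float, float] = 1.0,
    low_hz: float = 0.01,
    high_hz: float = 0.1,
    wm_signal: np.ndarray | None = None,
    csf_signal: np.ndarray | None = None,
) -> np.ndarray:
    """Full per-subject preparation on a 4D (x, y, z, t) volume.

    Order: nuisance regression -> smoothing -> band-pass. Returns the
    masked (n_voxels, T) matrix in ascending-linear-index voxel order.
    """
    volumes = np.asarray(volumes, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if volumes.shape[:3] != mask.shape:
        raise DataError("volume grid does not match mask")
    design = build_nuisance_design(motion, wm_signal, csf_signal)
    flat = volumes.reshape(-1, volumes.shape[-1])
    resid = regress_nuisance(flat, design).reshape(volumes.shape)
    smoothed = gaussian_smooth(resid, fwhm_mm, voxel_size_mm)
    filtered = bandpass(smoothed, tr_seconds, low_hz, high_hz)
    return filtered[mask]
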