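"""Composite cognitive scores and brain-behavior correlation.

Raw neuropsychological test scores are z-standardized against the pooled
cohort (optionally against the CN group only) and averaged into domain
composites. Circuit FC and composites are residualized on age, gender,
and education, then correlated with a percentile-bootstrap confidence
interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from bwaspipe.errors import (
    DataError,
    DegenerateCorrelationError,
    DegenerateDesignError,
    DegenerateTestError,
)
from bwaspipe.roi import bh_fdr

DEFAULT_RESIDUAL_COVARIATES = ("age", "gender", "education")


@dataclass
class CorrelationResult:
    circuit: str
    domain: str
    r: float
    p: float
    ci_low: float
    ci_high: float
    n_boot: int
    seed: int


def compute_composites(
    phenotype: pd.DataFrame,
    manifest: dict[str, list[str]],
    invert: set[str] | frozenset[str] = frozenset(),
    norm_group: str | None = None,
) -> pd.DataFrame:
    """Add per-domain composite z-score columns (``z_<domain>``).

    Each test is z-scored against the mean/SD of the norming sample
    (all included participants by default; ``norm_group='CN'`` for
    CN-referenced norms); tests listed in ``invert`` are sign-flipped
    so that higher always means better. The domain composite is the
    mean of its tests' z-scores.
    """
    out = phenotype.copy()
    if norm_group is not None:
        norm_rows = out["group"] == norm_group
        if not norm_rows.any():
            raise DataError(f"no subjects in norm group {norm_group!r}")
    else:
        norm_rows = pd.Series(True, index=out.index)
    for domain, tests in manifest.items():
        zs = []
        for test in tests:
            if test not in out.columns:
                raise DataError(f"phenotype table lacks test column {test!r}")
            vals = out[test].to_numpy(dtype=float)
            if np.any(~np.isfinite(vals)):
                raise DataError(f"test {test!r} has missing values")
            ref = vals[norm_rows.to_numpy()]
            sd = ref.std(ddof=1)
            if sd == 0:
                raise DegenerateTestError(
                    f"test {test!r} has zero variance in the norming sample"
                )
            z = (vals - ref.mean()) / sd
            zs.append(-z if test in invert else z)
        out[f"z_{domain}"] = np.mean(zs, axis=0)
    return out


def residualize(
    values: np.ndarray,
    covariates: np.ndarray,
) -> np.ndarray:
    """Least-squares residuals of ``values`` on intercept + covariates."""
    values = np.asarray(values, dtype=float)
    covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
    if covariates.shape[0] != len(values):
        covariates = covariates.T
    if covariates.shape[0] != len(values):
        raise DataError("covariate rows do not match value count")
    if len(values) <= covariates.shape[1] + 1:
        raise DataError("need n > covariate count + 1")
    x = np.column_stack([np.ones(len(values)), covariates])
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise DegenerateDesignError("collinear covariates in residualization")
    beta, *_ = np.linalg.lstsq(x, values, rcond=None)
    return values - x @ beta


def corr_bootstrap(
    fc_values: np.ndarray,
    cognition_values: np.ndarray,
    n_boot: int = 10_000,
    seed: int = 0,
    ci_level: float = 0.95,
) -> tuple[float, float, tuple[float, float]]:
    """Pearson r with two-tailed p and a percentile-bootstrap CI.

    Subjects are resampled in pairs; the CI is the percentile interval of
    the bootstrap r distribution. Reproducible from ``seed``.
    """
    x = np.asarray(fc_values, dtype=float)
    y = np.asarray(cognition_values, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DataError("fc and cognition values must be paired 1-D vectors")
    if len(x) < 5:
        raise DataError("need at least 5 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateCorrelationError("constant input vector")
    r, p = stats.pearsonr(x, y)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(x), size=(n_boot, len(x)))
    xb, yb = x[idx], y[idx]
    xb = xb - xb.mean(axis=1, keepdims=True)
    yb = yb - yb.mean(axis=1, keepdims=True)
    denom = np.sqrt((xb**2).sum(axis=1) * (yb**2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        rb = np.where(denom > 0, (xb * yb).sum(axis=1) / denom, np.nan)
    rb = rb[np.isfinite(rb)]
    tail = (1.0 - ci_level) / 2.0
    lo, hi = np.quantile(rb, [tail, 1.0 - tail])
    return float(r), float(p), (float(lo), float(hi))


def circuit_cognition_screen(
    circuit_fc: pd.DataFrame,
    phenotype: pd.DataFrame,
    domains: list[str] | None = None,
    covariates: tuple[str, ...] | list[str] = DEFAULT_RESIDUAL_COVARIATES,
    group: str | None = "SCD",
    n_boot: int = 10_000,
    seed: int = 0,
    adjust: bool = True,
) -> pd.DataFrame:
    """Correlate every (circuit, domain) pair after residualization.

    ``circuit_fc`` holds one column of Fisher-z FC per circuit, indexed
    by subject id; ``phenotype`` must already carry ``z_<domain>``
    composites. By default only the SCD subgroup enters. Raw p-values are
    reported; a BH-adjusted column is appended when ``adjust`` (clearly
    an optional extra — the primary read-out is unadjusted).
    """
    pheno = phenotype.set_index("subject_id")
    if group is not None:
        pheno = pheno[pheno["group"] == group]
        if pheno.empty:
            raise DataError(f"no subjects in group {group!r}")
    if domains is None:
        domains = [c[2:] for c in pheno.columns if c.startswith("z_")]
    if circuit_fc.empty or not list(circuit_fc.columns):
        raise DataError("need at least one circuit")
    fc = circuit_fc.loc[pheno.index]
    cov = pheno[list(covariates)].to_numpy(dtype=float)
    rows = []
    k = 0
    for circuit in fc.columns:
        fc_res = residualize(fc[circuit].to_numpy(dtype=float), cov)
        for domain in domains:
            cog_res = residualize(pheno[f"z_{domain}"].to_numpy(dtype=float), cov)
            r, p, (lo, hi) = corr_bootstrap(
                fc_res, cog_res, n_boot=n_boot, seed=seed + k
            )
            rows.append(
                {
                    "circuit": circuit,
                    "domain": domain,
                    "r": r,
                    "p": p,
                    "ci_low": lo,
                    "ci_high": hi,
                    "n": len(fc_res),
                    "n_boot": n_boot,
                }
            )
            k += 1
    out = pd.DataFrame(rows)
    if adjust and len(out):
        out["p_bh"] = bh_fdr(out["p"].to_numpy())
    return out
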