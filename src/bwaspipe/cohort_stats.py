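"""Demographic and neuropsychological group comparisons.

Pooled-variance two-sample Student t-tests (from raw vectors or printed
summary statistics) and the uncorrected Pearson chi-squared test for a
2x2 contingency table.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from bwaspipe.errors import DataError


def two_sample_t_from_summary(
    mean_a: float, sd_a: float, n_a: int,
    mean_b: float, sd_b: float, n_b: int,
) -> tuple[float, int, float]:
    """Pooled-variance Student t from group summaries.

    Returns (t, df, two-tailed p) with df = n_a + n_b - 2.
    """
    if n_a < 2 or n_b < 2:
        raise DataError("each group needs n >= 2")
    if sd_a < 0 or sd_b < 0:
        raise DataError("standard deviations must be nonnegative")
    df = n_a + n_b - 2
    pooled_var = ((n_a - 1) * sd_a**2 + (n_b - 1) * sd_b**2) / df
    se = np.sqrt(pooled_var * (1.0 / n_a + 1.0 / n_b))
    if se == 0:
        if mean_a == mean_b:
            raise DataError("undefined t: zero variance and equal means")
        t = np.inf if mean_a > mean_b else -np.inf
    else:
        t = (mean_a - mean_b) / se
    p = 2.0 * stats.t.sf(abs(t), df) if np.isfinite(t) else 0.0
    return float(t), df, float(p)


def two_sample_t(a, b) -> tuple[float, int, float]:
    """Pooled-variance two-sample t from raw vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return two_sample_t_from_summary(
        a.mean(), a.std(ddof=1), len(a), b.mean(), b.std(ddof=1), len(b)
    )


def chi_squared_2x2(a: int, b: int, c: int, d: int) -> tuple[float, int, float]:
    """Pearson chi-squared on the 2x2 table [[a, b], [c, d]], WITHOUT
    the Yates continuity correction. Returns (chi2, df=1, p)."""
    counts = np.array([a, b, c, d], dtype=float)
    if np.any(counts < 0):
        raise DataError("counts must be nonnegative")
    n = counts.sum()
    margins = [a + b, c + d, a + c, b + d]
    if any(m == 0 for m in margins) or n == 0:
        raise DataError("all table margins must be positive")
    chi2 = n * (a * d - b * c) ** 2 / np.prod(margins, dtype=float)
    p = float(stats.chi2.sf(chi2, 1))
    return float(chi2), 1, p


def demographics_table(
    phenotype: pd.DataFrame,
    continuous: tuple[str, ...] = ("age", "education", "itv", "mean_fd"),
) -> pd.DataFrame:
    """Group comparison report: mean (SD) per group with the pooled t for
    continuous variables and the chi-squared for gender."""
    cn = phenotype[phenotype["group"] == "CN"]
    scd = phenotype[phenotype["group"] == "SCD"]
    rows = []
    for col in continuous:
        if col not in phenotype.columns:
            continue
        t, df, p = two_sample_t(cn[col], scd[col])
        rows.append(
            {
                "characteristic": col,
                "cn": f"{cn[col].mean():.2f} ({cn[col].std(ddof=1):.2f})",
                "scd": f"{scd[col].mean():.2f} ({scd[col].std(ddof=1):.2f})",
                "statistic": t,
                "df": df,
                "p": p,
            }
        )
    if "gender" in phenotype.columns:
        men_cn = int((cn["gender"] == 1).sum())
        men_scd = int((scd["gender"] == 1).sum())
        chi2, df, p = chi_squared_2x2(
            men_cn, len(cn) - men_cn, men_scd, len(scd) - men_scd
        )
        rows.append(
            {
                "characteristic": "gender (men/women)",
                "cn": f"{men_cn}/{len(cn) - men_cn}",
                "scd": f"{men_scd}/{len(scd) - men_scd}",
                "statistic": chi2,
                "df": df,
                "p": p,
            }
        )
    return pd.DataFrame(rows)
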