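"""Lightweight report figures: a down-sampled link Manhattan scatter and
cognition-correlation scatter plots."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402

from bwaspipe.types import LinkTestTable  # noqa: E402


def manhattan_scatter(
    links: LinkTestTable,
    cutoff: float,
    out_path: Path | str,
    max_points: int = 50_000,
    seed: int = 0,
) -> None:
    """-log10(p) per link index, down-sampled; cutoff drawn in red."""
    p = np.clip(links.p_value, 1e-300, 1.0)
    idx = np.arange(len(p))
    if len(p) > max_points:
        rng = np.random.default_rng(seed)
        keep = rng.choice(len(p), size=max_points, replace=False)
        keep.sort()
        idx, p = idx[keep], p[keep]
    fig, ax = plt.subplots(figsize=(8, 3))
    ax.scatter(idx, -np.log10(p), s=2, alpha=0.5, linewidths=0)
    ax.axhline(-np.log10(cutoff), color="red", lw=1)
    ax.set_xlabel("link index")
    ax.set_ylabel("-log10 p")
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)


def correlation_scatter(
    fc_residuals: np.ndarray,
    cognition_residuals: np.ndarray,
    label: str,
    out_path: Path | str,
) -> None:
    """FC residual vs cognition residual with a least-squares fit line."""
    x = np.asarray(fc_residuals, dtype=float)
    y = np.asarray(cognition_residuals, dtype=float)
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(x, y, s=14)
    slope, intercept = np.polyfit(x, y, 1)
    xs = np.linspace(x.min(), x.max(), 50)
    ax.plot(xs, slope * xs + intercept, color="black", lw=1)
    ax.set_xlabel("FC (residual z)")
    ax.set_ylabel("cognition (residual z)")
    ax.set_title(label)
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
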