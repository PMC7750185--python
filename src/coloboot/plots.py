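"""Figures: coefficient distributions per selected variable, and the
stability-versus-p selection plane."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def plot_coefficient_distributions(
    archive: pd.DataFrame,
    summary: pd.DataFrame,
    stability_min: float = 10.0,
    ax=None,
):
    """Strip/violin of bootstrap coefficients for every level of every term
    with stability above *stability_min*; labels carry the stability in
    brackets and a vertical reference line marks zero."""
    if archive.empty:
        raise ValueError("empty replicate archive")
    keep = summary[summary["stability"] > stability_min]
    if ax is None:
        _, ax = plt.subplots(figsize=(8, max(2.5, 0.45 * max(len(keep), 1))))
    if keep.empty:
        ax.text(0.5, 0.5, "no variables above the stability threshold",
                ha="center", va="center", transform=ax.transAxes)
        ax.set_axis_off()
        return ax.figure
    keep = keep.sort_values("stability")
    rng = np.random.default_rng(0)  # jitter only, cosmetic
    for y_pos, (_, row) in enumerate(keep.iterrows()):
        vals = archive.loc[archive["label"] == row["label"], "coefficient"].dropna()
        jitter = rng.uniform(-0.18, 0.18, size=len(vals))
        ax.plot(vals, y_pos + jitter, ".", alpha=0.35, ms=4, color="tab:blue")
        ax.plot([row["mean_coef"]], [y_pos], "D", color="black", ms=5)
    ax.axvline(0.0, color="grey", lw=1)
    ax.set_yticks(range(len(keep)))
    ax.set_yticklabels(
        [f"{r['label']} ({r['stability']:.1f}%)" for _, r in keep.iterrows()]
    )
    ax.set_xlabel("coefficient (log cfu/ml)")
    ax.figure.tight_layout()
    return ax.figure


def plot_stability_vs_p(
    summary: pd.DataFrame,
    stability_min: float = 10.0,
    p_max: float = 0.025,
    ax=None,
):
    """Bootstrap p-value against stability per variable level, with the
    stability threshold as a dashed line and the p threshold as a dotted
    line."""
    if summary.empty:
        raise ValueError("empty stability summary")
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 5))
    ax.scatter(summary["stability"], summary["boot_p"], s=28, color="tab:blue")
    ax.axvline(stability_min, ls="--", color="black", lw=1)
    ax.axhline(p_max, ls=":", color="black", lw=1)
    ax.set_xlabel("stability (%)")
    ax.set_ylabel("bootstrap p-value")
    ax.figure.tight_layout()
    return ax.figure


def save_figure(fig, path_base) -> list[str]:
    """Write PNG and SVG variants of *fig*; returns the paths written."""
    paths = []
    for ext in ("png", "svg"):
        path = f"{path_base}.{ext}"
        fig.savefig(path, dpi=150)
        paths.append(path)
    plt.close(fig)
    return paths
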