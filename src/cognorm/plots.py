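"""Report figures for each pipeline stage (PNG, Agg backend)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["scree_plot", "normative_trajectory_plot", "posterior_interval_plot", "enrichment_plot"]


def scree_plot(explained_variance: np.ndarray, path: str | Path) -> Path:
    fig, ax = plt.subplots(figsize=(6, 4))
    pcs = np.arange(1, len(explained_variance) + 1)
    ax.bar(pcs, 100 * np.asarray(explained_variance), color="steelblue")
    ax.set_xlabel("principal component")
    ax.set_ylabel("explained variance (%)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def normative_trajectory_plot(model, demographics: pd.DataFrame, g: np.ndarray, path: str | Path) -> Path:
    """Predicted mean with +-1 and +-2 predictive-SD bands vs age, by sex."""
    from cognorm.normative import predict_gp

    fig, ax = plt.subplots(figsize=(7, 5))
    age = demographics["age"].to_numpy(dtype=float)
    sex = demographics["sex"].to_numpy(dtype=float)
    grid = np.linspace(age.min(), age.max(), 100)
    for sx, color in [(0, "tab:blue"), (1, "tab:red")]:
        pred = predict_gp(model, np.column_stack([grid, np.full_like(grid, sx)]))
        ax.plot(grid, pred.mean, color=color, label=f"sex={sx}")
        for w, alpha in [(1, 0.25), (2, 0.12)]:
            ax.fill_between(
                grid, pred.mean - w * pred.sd, pred.mean + w * pred.sd, color=color, alpha=alpha, lw=0
            )
        mask = sex == sx
        ax.scatter(age[mask], np.asarray(g)[mask], s=3, color=color, alpha=0.25)
    ax.set_xlabel("age (years)")
    ax.set_ylabel("general cognition (g)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def posterior_interval_plot(associations: pd.DataFrame, path: str | Path) -> Path:
    """Mean and 95% credible interval per predictor."""
    fig, ax = plt.subplots(figsize=(6, 0.45 * len(associations) + 1.5))
    ypos = np.arange(len(associations))[::-1]
    ax.errorbar(
        associations["beta_mean"],
        ypos,
        xerr=[
            associations["beta_mean"] - associations["ci_low"],
            associations["ci_high"] - associations["beta_mean"],
        ],
        fmt="o",
        color="firebrick",
        ecolor="gray",
        capsize=3,
    )
    ax.axvline(0.0, color="black", lw=0.8, ls="--")
    ax.set_yticks(ypos)
    ax.set_yticklabels(associations["predictor"])
    ax.set_xlabel("standardized coefficient (95% CI)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def enrichment_plot(enrichment: pd.DataFrame, path: str | Path, threshold: float = 2.0) -> Path:
    """Per-bin above-threshold proportion, one line per clinical domain."""
    fig, ax = plt.subplots(figsize=(7, 5))
    sub = enrichment[enrichment["threshold"] == threshold]
    for domain, grp in sub.groupby("domain"):
        ax.plot(grp["bin"], grp["proportion"], marker="o", label=domain)
    ax.set_xlabel("performance decile (1 = best)")
    ax.set_ylabel(f"proportion > {threshold} SD")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
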