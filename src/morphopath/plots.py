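"""Posterior visualisation: marginal density panels and forest plots."""

from __future__ import annotations

import logging
from pathlib import Path

import matplotlib

matplotlib.use("Agg")  # headless backend; figures are written, not shown
import matplotlib.pyplot as plt
import numpy as np

from .pathmodel import PosteriorDraws

__all__ = ["forest_plot", "density_panel", "forest_and_density_plots"]

log = logging.getLogger(__name__)


def forest_plot(summary, path: str | Path, parameters=None,
                title: str | None = None) -> Path:
    """Mean and 95%-interval bars, one row per parameter."""
    if parameters is not None:
        present = [p for p in parameters if p in summary.index]
        for p in set(parameters) - set(present):
            log.info("forest plot: parameter %s absent from model; skipped", p)
        summary = summary.loc[present]
    n = len(summary)
    fig, ax = plt.subplots(figsize=(7, max(2, 0.3 * n + 1)))
    y = np.arange(n)[::-1]
    ax.errorbar(summary["mean"], y,
                xerr=[summary["mean"] - summary["lower95"],
                      summary["upper95"] - summary["mean"]],
                fmt="o", color="black", ecolor="black", capsize=2,
                markersize=3)
    ax.axvline(0.0, color="grey", lw=0.8, ls="--")
    ax.set_yticks(y)
    ax.set_yticklabels(summary.index, fontsize=7)
    ax.set_xlabel("posterior mean and 95% interval (standardised scale)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def density_panel(draws: PosteriorDraws, path: str | Path, parameters=None,
                  title: str | None = None) -> Path:
    """Marginal posterior densities with mean and 95% interval bars.

    Degenerate (constant) margins are rendered as a vertical spike with a
    zero-width bar.
    """
    names = draws.parameter_names
    if parameters is None:
        parameters = names
    present = [p for p in parameters if p in names]
    for p in set(parameters) - set(present):
        log.info("density panel: parameter %s absent from model; skipped", p)
    flat = draws.flat
    n = len(present)
    ncol = min(4, max(1, n))
    nrow = int(np.ceil(n / ncol))
    fig, axes = plt.subplots(nrow, ncol, figsize=(3 * ncol, 2.2 * nrow),
                             squeeze=False)
    for k, p in enumerate(present):
        ax = axes[k // ncol][k % ncol]
        x = flat[:, names.index(p)]
        lo, hi = np.percentile(x, [2.5, 97.5])
        if np.ptp(x) == 0:
            ax.axvline(x[0], color="C0")
            ax.plot([x[0], x[0]], [0, 0], lw=3, color="black")
        else:
            ax.hist(x, bins=60, density=True, color="C0", alpha=0.7)
            ymax = ax.get_ylim()[1]
            ax.plot([lo, hi], [-0.02 * ymax] * 2, lw=2, color="black")
            ax.plot(x.mean(), -0.02 * ymax, "o", color="black", ms=4)
        ax.set_title(p, fontsize=7)
        ax.set_yticks([])
    for k in range(n, nrow * ncol):
        axes[k // ncol][k % ncol].axis("off")
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def forest_and_density_plots(summary, draws: PosteriorDraws,
                             out_dir: str | Path,
                             prefix: str = "model") -> dict[str, Path]:
    """Write the standard figure pair for one fitted model."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    slope_names = [p for p in draws.parameter_names if p.startswith("slope[")]
    corr_names = [p for p in draws.parameter_names if p.startswith("corr[")]
    return {
        "forest": forest_plot(summary, out_dir / f"{prefix}_forest.png",
                              parameters=slope_names + corr_names),
        "density": density_panel(draws, out_dir / f"{prefix}_density.png",
                                 parameters=slope_names + corr_names),
    }
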