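"""Optional matplotlib renderings: heatmap, tuning curve, dose-response curve."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .dose_response import DoseResponseFit
from .tuning import tuning_curve

__all__ = ["plot_heatmap", "plot_tuning_curve", "plot_dose_response"]


def plot_heatmap(table: pd.DataFrame, path: str | Path) -> None:
    """Receptor x odorant heatmap from a wide mean-response table."""
    fig, ax = plt.subplots(figsize=(max(6, 0.3 * table.shape[1]), 3))
    im = ax.imshow(table.to_numpy(), aspect="auto", cmap="viridis")
    ax.set_yticks(range(table.shape[0]), table.index)
    ax.set_xticks(range(table.shape[1]), table.columns, rotation=90,
                  fontsize=6)
    fig.colorbar(im, ax=ax, label="mean Δ spikes/s")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_tuning_curve(means: np.ndarray | dict, path: str | Path) -> None:
    """Bell-ordered tuning curve of mean responses."""
    ordered = tuning_curve(means)
    fig, ax = plt.subplots(figsize=(6, 3))
    ax.bar(range(len(ordered)), ordered, color="0.3")
    ax.set_xlabel("odorant (bell order)")
    ax.set_ylabel("mean Δ spikes/s")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_dose_response(fit: DoseResponseFit, doses: np.ndarray,
                       responses: np.ndarray, path: str | Path) -> None:
    """Per-dose mean ± SEM with the fitted log-logistic curve."""
    doses = np.asarray(doses, dtype=float)
    responses = np.asarray(responses, dtype=float)
    uniq = np.unique(doses)
    means = [responses[doses == d].mean() for d in uniq]
    sems = [responses[doses == d].std(ddof=1) / np.sqrt((doses == d).sum())
            if (doses == d).sum() > 1 else 0.0 for d in uniq]
    grid = np.logspace(np.log10(uniq.min()), np.log10(uniq.max()), 200)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.errorbar(uniq, means, yerr=sems, fmt="o", color="k", capsize=3)
    ax.plot(grid, fit.predict(grid), color="crimson",
            label=f"ED50 = {fit.ed50:.3g} ng")
    ax.set_xscale("log")
    ax.set_xlabel("dose (ng)")
    ax.set_ylabel("Δ spikes/s")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
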