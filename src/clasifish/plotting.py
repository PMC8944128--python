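"""Minimal figures: correlation ensembles and density summaries."""

from __future__ import annotations

import numpy as np

from .dipole import CurveEnsemble

__all__ = ["plot_ensemble", "plot_density_report"]


def plot_ensemble(ensemble: CurveEnsemble, ax=None, label: str | None = None):
    """Mean pair-correlation curve with its 95% CI ribbon and the g=1 line."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.2))
    ax.plot(ensemble.distance_um, ensemble.mean, lw=1.5, label=label)
    if ensemble.ci_low is not None:
        ax.fill_between(
            ensemble.distance_um, ensemble.ci_low, ensemble.ci_high, alpha=0.25
        )
    ax.axhline(1.0, color="k", lw=0.8, ls="--")
    ax.set_xlabel("distance (µm)")
    ax.set_ylabel("pair correlation g(r)")
    if label:
        ax.legend(frameon=False)
    return ax


def plot_density_report(report, ax=None, group_col: str = "site"):
    """Grouped bar plot of cells/cm^2 per taxon (log scale)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3.2))
    taxa = sorted(report.taxon.unique())
    groups = sorted(report[group_col].unique())
    width = 0.8 / max(len(groups), 1)
    x = np.arange(len(taxa))
    for i, grp in enumerate(groups):
        sub = report[report[group_col] == grp].set_index("taxon")
        vals = [sub.cells_per_cm2.get(t, np.nan) for t in taxa]
        ax.bar(x + i * width, vals, width, label=str(grp))
    ax.set_xticks(x + 0.4 - width / 2)
    ax.set_xticklabels(taxa, rotation=30, ha="right", fontsize=8)
    ax.set_yscale("log")
    ax.set_ylabel("cells / cm$^2$")
    ax.legend(frameon=False, fontsize=8)
    return ax
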