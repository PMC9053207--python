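"""Optional figure rendering: forest plot of site contrasts and a
TMB-high percentage-difference heatmap."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def forest_plot(contrasts: pd.DataFrame, path: str | None = None):
    """Dot-and-interval grid: rows = biopsy sites, columns = cancer types.

    Expects the contrast table of :func:`tmbsite.emm.run_all` (estimate and
    95% CI in mut/Mb); the reference site sits at 0.
    """
    cancers = sorted(contrasts["cancer_type"].dropna().unique())
    sites = sorted(contrasts["site"].unique())
    fig, axes = plt.subplots(
        1, max(len(cancers), 1), figsize=(3 * max(len(cancers), 1), 0.4 * len(sites) + 1.5),
        sharey=True, squeeze=False,
    )
    ypos = {s: i for i, s in enumerate(sites)}
    for ax, cancer in zip(axes[0], cancers):
        sub = contrasts[contrasts["cancer_type"] == cancer]
        for r in sub.itertuples(index=False):
            y = ypos[r.site]
            ax.plot([r.ci_low, r.ci_high], [y, y], color="0.4", lw=1)
            ax.plot(r.estimate, y, "o", color="tab:blue", ms=4)
        ax.axvline(0, color="0.8", lw=0.8)
        ax.set_title(str(cancer), fontsize=9)
        ax.set_xlabel("difference (mut/Mb)", fontsize=8)
    axes[0][0].set_yticks(range(len(sites)), sites)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def pct_difference_heatmap(results: pd.DataFrame, path: str | None = None):
    """Heatmap of TMB-high percentage-point differences vs the reference."""
    pivot = results.pivot_table(
        index="site", columns="cancer_type", values="pct_difference", aggfunc="first"
    )
    fig, ax = plt.subplots(figsize=(1 + 0.8 * pivot.shape[1], 1 + 0.4 * pivot.shape[0]))
    vmax = np.nanmax(np.abs(pivot.to_numpy())) if pivot.size else 1.0
    im = ax.imshow(pivot.to_numpy(float), cmap="RdBu_r", vmin=-vmax, vmax=vmax, aspect="auto")
    ax.set_xticks(range(pivot.shape[1]), pivot.columns, rotation=45, ha="right", fontsize=8)
    ax.set_yticks(range(pivot.shape[0]), pivot.index, fontsize=8)
    fig.colorbar(im, ax=ax, label="TMB-high difference (pct points)")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
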