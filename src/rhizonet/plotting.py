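"""Minimal figures: the module × trait association heat map."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .modules import AssociationMatrix


def association_heatmap(
    am: AssociationMatrix,
    path: str | Path,
    title: str = "Module-trait associations",
) -> None:
    """Spearman-rho heat map with significant cells (p < alpha) outlined."""
    rho = am.rho.astype(float)
    fig, ax = plt.subplots(
        figsize=(max(4.0, 0.4 * rho.shape[1] + 2), max(2.5, 0.5 * rho.shape[0] + 1.5))
    )
    im = ax.pcolormesh(rho.to_numpy(), cmap="RdBu_r", vmin=-1, vmax=1,
                       edgecolors="white", linewidth=0.5)
    sig = am.significant.to_numpy()
    for i in range(rho.shape[0]):
        for j in range(rho.shape[1]):
            if sig[i, j]:
                ax.add_patch(plt.Rectangle((j, i), 1, 1, fill=False,
                                           edgecolor="green", linewidth=1.5))
    ax.set_xticks(np.arange(rho.shape[1]) + 0.5, rho.columns, rotation=90, fontsize=7)
    ax.set_yticks(np.arange(rho.shape[0]) + 0.5, rho.index, fontsize=8)
    ax.set_title(title, fontsize=10)
    fig.colorbar(im, ax=ax, label="Spearman rho")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
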