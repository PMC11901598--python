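"""Threshold point plot for pairwise shared heterozygosity."""

from __future__ import annotations

import logging
import os

import numpy as np

from .clonality import SHResult

logger = logging.getLogger("polyshare")


def plot_sh_points(result: SHResult, path: str | os.PathLike, seed: int = 0) -> None:
    """One point per sample pair, grouped by lineage on the x axis, with a
    horizontal line at the clone threshold.  Pairs with undefined SH are
    skipped (with a warning if nothing remains)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    defined = [p for p in result.pairs if p.sh is not None]
    lineages = sorted({p.lineage for p in defined})
    fig, ax = plt.subplots(figsize=(max(4, 0.9 * len(lineages) + 2), 4))
    if not defined:
        logger.warning("SH plot: no pair has a defined SH value; writing empty plot")
    rng = np.random.default_rng(seed)  # jitter only
    cmap = plt.get_cmap("tab10")
    for k, lin in enumerate(lineages):
        ys = [p.sh for p in defined if p.lineage == lin]
        xs = k + rng.uniform(-0.18, 0.18, size=len(ys))
        ax.scatter(xs, ys, s=18, color=cmap(k % 10), label=lin, zorder=3)
    ax.axhline(result.threshold, color="deeppink", lw=1.2, zorder=2)
    ax.set_xticks(range(len(lineages)))
    ax.set_xticklabels(lineages, rotation=45, ha="right", fontsize=8)
    ax.set_ylabel("shared heterozygosity (SH)")
    ax.set_ylim(-0.02, 1.02)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
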