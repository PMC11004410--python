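"""Dot-and-bar figure for fold-change point sets.

Replicates the presentation style of the fold-change statistic: individual
fold-change points, a black median bar, and light/dark gray bars marking
the 68% and 95% percentile bands.
"""

from __future__ import annotations

import numpy as np

from .stats import FoldChangeSummary


def fold_change_figure(summaries: list[FoldChangeSummary],
                       points: list[np.ndarray] | None = None,
                       ax=None, max_points: int = 400, rng=0):
    """Plot one dot-and-bar column per condition summary.

    ``points`` optionally supplies the raw fold-change point set for each
    summary (subsampled to ``max_points`` for display; the bars always come
    from the summary's full-set percentiles).  The y-axis is logarithmic.
    Returns the matplotlib axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(1.2 * len(summaries) + 1, 4))
    rng = np.random.default_rng(rng)
    for i, s in enumerate(summaries):
        if points is not None:
            pts = np.asarray(points[i])
            if len(pts) > max_points:
                pts = rng.choice(pts, max_points, replace=False)
            x = i + rng.uniform(-0.18, 0.18, len(pts))
            ax.scatter(x, pts, s=6, alpha=0.35, color=f"C{i}", linewidths=0)
        for edge in s.band95:
            ax.plot([i - 0.3, i + 0.3], [edge] * 2, color="0.35", lw=2)
        for edge in s.band68:
            ax.plot([i - 0.25, i + 0.25], [edge] * 2, color="0.7", lw=3)
        ax.plot([i - 0.3, i + 0.3], [s.median] * 2, color="k", lw=2.5)
    ax.axhline(1.0, color="k", ls=":", lw=0.8)
    ax.set_yscale("log")
    ax.set_xticks(range(len(summaries)))
    ax.set_xticklabels([s.condition_label for s in summaries])
    ax.set_ylabel("fold change vs control")
    return ax
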