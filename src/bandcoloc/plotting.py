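"""Figure helpers: condition bar plots, coverage heatmaps, composite plots."""

from __future__ import annotations

import numpy as np

from .coloc import ConditionData
from .genomic import CoverageMatrix


def plot_condition_means(conditions: list[ConditionData], ax=None):
    """Bar of per-condition mean percentage with per-larva points overlaid."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(1.2 + 0.9 * len(conditions), 3.2))
    rng = np.random.default_rng(0)  # jitter for point visibility only
    for i, cond in enumerate(conditions):
        ax.bar(i, cond.mean, width=0.6, color="0.8", edgecolor="black", zorder=1)
        x = i + rng.uniform(-0.12, 0.12, cond.n_larvae)
        ax.scatter(x, cond.values, s=18, color="black", zorder=2)
    ax.set_xticks(range(len(conditions)))
    ax.set_xticklabels([c.condition for c in conditions], rotation=30, ha="right")
    ax.set_ylabel("co-occurring bands (% of total bands)")
    ax.set_ylim(0, 100)
    return ax


def plot_heatmap(matrix: CoverageMatrix, order: np.ndarray | None = None, ax=None,
                 title: str = ""):
    """Peak-centered heatmap; rows optionally reordered by a signal sort."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(3, 4))
    values = matrix.values if order is None else matrix.values[order]
    half = matrix.window_bp // 2
    ax.imshow(
        values,
        aspect="auto",
        interpolation="nearest",
        extent=(-half, half, values.shape[0], 0),
        cmap="viridis",
    )
    ax.set_xlabel("distance from peak midpoint (bp)")
    ax.set_ylabel("peaks")
    if title:
        ax.set_title(title)
    return ax


def plot_composite(profiles: dict[str, np.ndarray], window_bp: int, ax=None):
    """Composite (mean-across-peaks) profiles, one line per labelled track."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    half = window_bp // 2
    x = np.arange(-half, half)
    for label, values in profiles.items():
        ax.plot(x, values, label=label)
    ax.set_xlabel("distance from peak midpoint (bp)")
    ax.set_ylabel("mean log2 coverage")
    ax.legend(frameon=False, fontsize=8)
    return ax
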