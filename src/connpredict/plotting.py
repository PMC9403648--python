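"""Minimal plotting: network-cell heatmaps of weight summaries."""

from __future__ import annotations

import numpy as np


def network_cell_heatmap(cells, *, column: str = "mean_weight", ax=None):
    """Heatmap of a per-network-pair summary on the K × K network grid.

    ``cells`` is the table produced by
    :func:`connpredict.interpretation.network_summary`.  Returns the axes.
    """
    import matplotlib.pyplot as plt

    names = list(dict.fromkeys(cells["net_a"]))
    for n in cells["net_b"]:
        if n not in names:
            names.append(n)
    k = len(names)
    grid = np.full((k, k), np.nan)
    idx = {n: i for i, n in enumerate(names)}
    for _, row in cells.iterrows():
        a, b = idx[row["net_a"]], idx[row["net_b"]]
        grid[a, b] = grid[b, a] = row[column]
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    vmax = np.nanmax(np.abs(grid))
    im = ax.imshow(grid, cmap="RdBu_r", vmin=-vmax, vmax=vmax)
    ax.set_xticks(range(k), names, rotation=45, ha="right")
    ax.set_yticks(range(k), names)
    ax.figure.colorbar(im, ax=ax, label=column)
    return ax
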