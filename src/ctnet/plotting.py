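"""Plot helpers for percent matrices and consensus networks."""

from __future__ import annotations

import numpy as np


def plot_percent_matrix(results, ax=None, cmap: str = "RdYlGn"):
    """Heatmap of the aligned percent matrix (red = cold, green = hot)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    df = results.percent_matrix
    im = ax.imshow(df.to_numpy(), cmap=cmap, vmin=0, vmax=max(1.0, df.to_numpy().max()))
    ax.set_xticks(np.arange(len(df)), df.columns, rotation=90, fontsize=7)
    ax.set_yticks(np.arange(len(df)), df.index, fontsize=7)
    ax.figure.colorbar(im, ax=ax, label="% of nuclei")
    ax.set_title("aligned interaction percent matrix")
    return ax


def plot_network(network, ax=None, seed: int = 0):
    """Consensus network; line width encodes the percent tier."""
    import matplotlib.pyplot as plt
    import networkx as nx

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    g = network.to_networkx()
    pos = nx.circular_layout(g) if len(g) > 1 else {n: (0, 0) for n in g}
    widths = {"top": 3.0, "middle": 1.8, "bottom": 0.8}
    nx.draw_networkx_nodes(g, pos, ax=ax, node_size=350, node_color="#dddddd")
    nx.draw_networkx_labels(g, pos, ax=ax, font_size=8)
    for u, v, d in g.edges(data=True):
        nx.draw_networkx_edges(
            g, pos, edgelist=[(u, v)], ax=ax, width=widths[d["tier"]]
        )
    ax.set_axis_off()
    ax.set_title(f"consensus network (τ = {network.threshold:.0f}%)")
    return ax
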