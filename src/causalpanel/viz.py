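"""Minimal rendering helper for discovered graphs."""
from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import networkx as nx

from .graphs import CausalGraph

__all__ = ["plot_graph"]


def plot_graph(graph: CausalGraph, path=None, ax=None):
    """Draw the cross-link graph; edge labels give the lag in days.

    Unoriented or conflicted contemporaneous links are drawn dashed.
    """
    g = nx.MultiDiGraph()
    names = graph.names or [str(i) for i in range(graph.n_vars)]
    g.add_nodes_from(names)
    for link in graph.cross_links():
        g.add_edge(
            names[link.source],
            names[link.sink],
            lag=link.lag,
            style="dashed" if link.orientation != "directed" else "solid",
        )
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 7))
    pos = nx.circular_layout(g)
    nx.draw_networkx_nodes(g, pos, ax=ax, node_color="#dfe8f3", node_size=2600)
    nx.draw_networkx_labels(g, pos, ax=ax, font_size=8)
    for u, v, data in g.edges(data=True):
        ax.annotate(
            "",
            xy=pos[v],
            xytext=pos[u],
            arrowprops=dict(
                arrowstyle="-|>" if data["style"] == "solid" else "-",
                linestyle=data["style"],
                connectionstyle="arc3,rad=0.12",
                color="tab:gray",
            ),
        )
        mid = (pos[u] + pos[v]) / 2
        ax.text(mid[0], mid[1], str(data["lag"]), fontsize=7, color="tab:red")
    ax.set_axis_off()
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
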