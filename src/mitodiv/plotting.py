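"""Optional figure helpers (require matplotlib)."""

from __future__ import annotations

import networkx as nx


def plot_accumulation(curves: dict, ax=None, vline_at_min_n: bool = True):
    """Mean +/- SD ribbon per group for accumulation curves.

    ``curves`` maps group label -> :class:`~mitodiv.rarefaction.AccumulationCurve`.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for label, c in curves.items():
        ax.plot(c.g, c.mean, label=label)
        ax.fill_between(c.g, c.mean - c.se, c.mean + c.se, alpha=0.25)
    if vline_at_min_n and curves:
        ax.axvline(min(c.g[-1] for c in curves.values()), ls="--", color="k", lw=0.8)
    ax.set_xlabel("sequences sampled (g)")
    ax.set_ylabel("accumulated haplotypes")
    ax.legend()
    return ax


def plot_network(g: nx.Graph, ax=None, seed: int = 0):
    """Force-directed sketch: sampled nodes sized by count, medians as dots."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    pos = nx.spring_layout(g, seed=seed, weight="weight")
    sizes, colors = [], []
    for node, attrs in g.nodes(data=True):
        total = sum(v for k, v in attrs.items() if k.startswith("count_"))
        if attrs.get("kind") == "median":
            sizes.append(30)
            colors.append("black")
        else:
            sizes.append(100 + 60 * total)
            colors.append("tab:blue")
    nx.draw_networkx(g, pos=pos, ax=ax, node_size=sizes, node_color=colors,
                     font_size=7, with_labels=True)
    nx.draw_networkx_edge_labels(
        g, pos=pos, ax=ax, font_size=7,
        edge_labels={e: f"({g.edges[e]['weight']})" for e in g.edges},
    )
    ax.set_axis_off()
    return ax
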