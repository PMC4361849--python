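"""Diagnostic plots: disconnectivity diagram and MDS embedding scatter."""

from __future__ import annotations

import numpy as np

from .trdg import TRDGNode, TRDGTree

__all__ = ["plot_trdg", "plot_mds", "trdg_plot_coordinates"]


def _layout(node: TRDGNode, x0: float, coords: dict) -> tuple[float, float]:
    """Assign leaf x positions left-to-right; return (x_center, next_free_x)."""
    if node.is_leaf:
        coords[id(node)] = (x0, node.energy)
        return x0, x0 + 1.0
    xs = []
    x = x0
    for child in node.children:
        cx, x = _layout(child, x, coords)
        xs.append(cx)
    cx = float(np.mean(xs))
    coords[id(node)] = (cx, node.energy)
    return cx, x


def trdg_plot_coordinates(tree: TRDGTree) -> list[dict]:
    """Plot coordinates for a disconnectivity diagram (also exportable as
    TSV rows): one record per node with x, energy, and parent linkage."""
    coords: dict = {}
    _layout(tree.root, 0.0, coords)
    rows = []

    def walk(node: TRDGNode, parent: TRDGNode | None):
        x, e = coords[id(node)]
        px, pe = coords[id(parent)] if parent is not None else (x, e)
        rows.append(
            {
                "states": "+".join(map(str, node.states)),
                "x": x,
                "energy": e,
                "parent_x": px,
                "parent_energy": pe,
                "is_leaf": node.is_leaf,
                "cut_order": node.cut_order,
            }
        )
        for c in node.children:
            walk(c, node)

    walk(tree.root, None)
    return rows


def plot_trdg(tree: TRDGTree, ax=None):
    """Draw the classic disconnectivity 'candelabra': vertical drops from
    each barrier to its children, leaves labeled with their state id."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 5))
    rows = trdg_plot_coordinates(tree)
    for r in rows:
        ax.plot([r["parent_x"], r["x"]], [r["parent_energy"], r["parent_energy"]], color="k", lw=1)
        ax.plot([r["x"], r["x"]], [r["parent_energy"], r["energy"]], color="k", lw=1)
        if r["is_leaf"]:
            ax.annotate(
                f"S{r['states']}",
                (r["x"], r["energy"]),
                textcoords="offset points",
                xytext=(0, -12),
                ha="center",
                fontsize=8,
            )
        elif r["cut_order"] is not None:
            ax.annotate(
                str(r["cut_order"]),
                (r["x"], r["energy"]),
                textcoords="offset points",
                xytext=(4, 2),
                fontsize=7,
            )
    ax.set_ylabel("free energy (kcal/mol)")
    ax.set_xticks([])
    return ax


def plot_mds(coords: np.ndarray, labels: np.ndarray | None = None, ax=None):
    """Scatter the first two MDS coordinates, colored by state label."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    coords = np.asarray(coords)
    if coords.shape[1] < 2:
        coords = np.column_stack([coords[:, 0], np.zeros(len(coords))])
    sc = ax.scatter(coords[:, 0], coords[:, 1], c=labels, s=12, cmap="viridis")
    if labels is not None:
        plt.colorbar(sc, ax=ax, label="state")
    ax.set_xlabel("MDS 1")
    ax.set_ylabel("MDS 2")
    return ax
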