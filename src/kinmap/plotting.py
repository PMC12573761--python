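"""Figure export for kinetics-map runs (vector graphics, best effort)."""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["export_figures"]


def _save(fig, path: Path) -> None:
    # drop the embedded creation date so identical runs write identical bytes
    meta = {"Date": None} if path.suffix == ".svg" else None
    fig.savefig(path, bbox_inches="tight", metadata=meta)


def _project(x: np.ndarray) -> np.ndarray:
    """First two coordinates of a state (2D systems plot natively)."""
    flat = np.asarray(x).reshape(len(x), -1) if np.ndim(x) > 1 else np.asarray(x)
    return flat[:, :2] if flat.ndim == 2 else flat[:2]


def export_figures(out_dir, states=None, chi=None, graph=None, weights=None,
                   pathways=None, beta: float = 1.0, fmt: str = "svg") -> list:
    """Write up to three figures: chi-colored state scatter, the map
    projected onto state space, and free-energy profiles per pathway.

    Missing inputs skip the corresponding figure with a warning; the
    list of written files is returned.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []

    if states is not None and chi is not None:
        fig, ax = plt.subplots(figsize=(5, 4))
        xy = np.asarray(states).reshape(len(states), -1)
        sc = ax.scatter(xy[:, 0], xy[:, 1], c=chi, cmap="coolwarm", s=4,
                        vmin=0, vmax=1)
        fig.colorbar(sc, ax=ax, label=r"$\chi$")
        ax.set_xlabel("x"); ax.set_ylabel("y")
        ax.set_title("States colored by membership function")
        path = out_dir / f"chi_scatter.{fmt}"
        _save(fig, path); plt.close(fig)
        written.append(path)
    else:
        logger.warning("chi scatter skipped: states or chi missing")

    if graph is not None and len(graph.nodes):
        fig, ax = plt.subplots(figsize=(5, 4))
        if states is not None:
            xy = np.asarray(states).reshape(len(states), -1)
            ax.scatter(xy[:, 0], xy[:, 1], c="0.8", s=3, zorder=0)
        pos = {n.node_id: _project(np.asarray(n.mean_structure)[None])[0]
               for n in graph.nodes}
        for (i, j), w in graph.edges.items():
            a, b = pos[i], pos[j]
            ax.plot([a[0], b[0]], [a[1], b[1]], "k-", lw=1 + np.log1p(w), zorder=1)
        chis = [n.mean_chi for n in graph.nodes]
        sizes = [200 * max(n.weight, 0.05) + 30 for n in graph.nodes]
        ax.scatter([pos[n.node_id][0] for n in graph.nodes],
                   [pos[n.node_id][1] for n in graph.nodes],
                   c=chis, cmap="coolwarm", s=sizes, vmin=0, vmax=1,
                   edgecolor="k", zorder=2)
        ax.set_title("Molecular Kinetics Map")
        path = out_dir / f"mkm.{fmt}"
        _save(fig, path); plt.close(fig)
        written.append(path)
    else:
        logger.warning("map figure skipped: graph missing")

    if graph is not None and weights is not None and pathways:
        fig, ax = plt.subplots(figsize=(5, 4))
        for k, p in enumerate(pathways):
            chis = [graph.nodes[i].mean_chi for i in p.nodes]
            energies = [-np.log(weights.of(i)) / beta for i in p.nodes]
            ax.plot(chis, energies, "o-", label=f"pathway {k}")
        ax.set_xlabel(r"$\chi$")
        ax.set_ylabel(r"free energy ($k_BT$)" if beta == 1.0 else "free energy")
        ax.legend()
        ax.set_title("Free-energy profiles along pathways")
        path = out_dir / f"profiles.{fmt}"
        _save(fig, path); plt.close(fig)
        written.append(path)
    else:
        logger.warning("profile figure skipped: graph, weights or pathways missing")
    return written
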