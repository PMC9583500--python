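"""Export each unbalanced process as a weighted, signed marker subnetwork.

Nodes are markers whose participation weight in the process passes a cut;
the node direction (up/down) is the sign of the mean deviation
``G_ia * lambda_a(cell)`` over a chosen subset of cells. Interaction edges
are imported from a pre-downloaded pair list (e.g. a STRING export) and
filtered to the node set — no live database access.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .barcoding import BarcodeAssignment
from .sa import Decomposition

__all__ = ["ProcessNetwork", "build_process_network", "default_g_cut", "read_edge_list"]


def default_g_cut(n_markers: int) -> float:
    """Heuristic participation cut ``1.96 / sqrt(n_markers)``.

    Under a flat (uninformative) orthonormal pattern every |G| entry is about
    ``1 / sqrt(n_markers)``; the factor 1.96 asks for roughly twice that.
    """
    return 1.96 / np.sqrt(n_markers)


@dataclass
class ProcessNetwork:
    """Signed marker subnetwork of one unbalanced process."""

    alpha: int
    nodes: pd.DataFrame          # index marker, columns: weight, direction
    edges: list[tuple[str, str]] = field(default_factory=list)
    g_cut: float = 0.0
    cell_subset: str = "all"

    def to_graph(self) -> nx.Graph:
        g = nx.Graph(process=self.alpha, g_cut=self.g_cut, cell_subset=self.cell_subset)
        for marker, row in self.nodes.iterrows():
            g.add_node(marker, weight=float(row["weight"]), direction=row["direction"],
                       size=abs(float(row["weight"])))
        g.add_edges_from(self.edges)
        return g


def read_edge_list(path: str | Path) -> list[tuple[str, str]]:
    """Two-column delimited identifier pairs (extra columns ignored)."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: edge list needs at least two columns")
    return [(str(a), str(b)) for a, b in zip(df.iloc[:, 0], df.iloc[:, 1])]


def build_process_network(
    dec: Decomposition,
    bars: BarcodeAssignment | None,
    alpha: int,
    g_cut: float | None = None,
    cell_subset: str = "active_positive",
    edges: list[tuple[str, str]] | None = None,
) -> ProcessNetwork:
    """Build the marker subnetwork of process ``alpha``.

    Parameters
    ----------
    dec : fitted decomposition.
    bars : barcode assignment used to pick the cell subset; may be None when
        ``cell_subset="all"``.
    alpha : process index, 1-based.
    g_cut : keep markers with ``|G_ia| >= g_cut``; defaults to
        :func:`default_g_cut`.
    cell_subset : {"active_positive", "active_negative", "all"} — cells over
        which the mean deviation (hence node direction) is taken.
    edges : optional imported interaction pairs, filtered to the node set.
    """
    if not 1 <= alpha <= dec.n_processes:
        raise IndexError(f"alpha must be in 1..{dec.n_processes}, got {alpha}")
    if g_cut is None:
        g_cut = default_g_cut(len(dec.marker_names))
    if g_cut < 0:
        raise ValueError("g_cut must be >= 0")
    if cell_subset not in ("active_positive", "active_negative", "all"):
        raise ValueError(f"unknown cell_subset {cell_subset!r}")

    g_col = dec.G[:, alpha]
    lam = dec.Lambda[:, alpha]
    if cell_subset == "all":
        mask = np.ones(dec.n_cells, dtype=bool)
    else:
        if bars is None:
            raise ValueError("barcodes required for an active-cell subset")
        if bars.mode != "signed":
            raise ValueError("active_positive/active_negative subsets need signed barcodes")
        want = 1 if cell_subset == "active_positive" else -1
        mask = bars.codes[:, alpha - 1] == want

    keep = np.abs(g_col) >= g_cut
    markers = [m for m, k in zip(dec.marker_names, keep) if k]
    if not markers:
        warnings.warn(f"process {alpha}: no marker passes g_cut={g_cut:.3g}; empty network",
                      RuntimeWarning, stacklevel=2)

    if mask.any():
        mean_lam = float(lam[mask].mean())
    else:
        mean_lam = 0.0
    weights = g_col[keep]
    direction = np.where(weights * mean_lam > 0, "up",
                         np.where(weights * mean_lam < 0, "down", "none"))
    nodes = pd.DataFrame({"weight": weights, "direction": direction},
                         index=pd.Index(markers, name="marker"))
    kept_edges = []
    if edges:
        node_set = set(markers)
        kept_edges = [(a, b) for a, b in edges if a in node_set and b in node_set]
    return ProcessNetwork(alpha=alpha, nodes=nodes, edges=kept_edges,
                          g_cut=float(g_cut), cell_subset=cell_subset)
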