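"""Reading and writing symptom networks.

Supported formats: square adjacency CSV (header row and label column),
weighted edge-list TSV (``source<TAB>target<TAB>weight``) and GraphML.
Asymmetric adjacency input is symmetrized by averaging with a warning,
since directed estimates (e.g. nodewise regressions) are routinely
reconciled this way.
"""

from __future__ import annotations

import logging
import os
from typing import Literal

import networkx as nx
import numpy as np
import pandas as pd

from .network import SymptomNetwork

__all__ = ["read_network", "write_network"]

log = logging.getLogger(__name__)

Format = Literal["adjacency-csv", "edgelist-tsv", "graphml"]

_EXT_TO_FORMAT: dict[str, Format] = {
    ".csv": "adjacency-csv",
    ".tsv": "edgelist-tsv",
    ".graphml": "graphml",
}


def _infer_format(path: str) -> Format:
    ext = os.path.splitext(path)[1].lower()
    if ext not in _EXT_TO_FORMAT:
        raise ValueError(f"cannot infer network format from extension {ext!r}")
    return _EXT_TO_FORMAT[ext]


def read_network(path: str, format: Format | None = None) -> SymptomNetwork:
    """Load a :class:`SymptomNetwork` from disk.

    Raises ``ValueError`` for non-square adjacency, duplicate labels or
    missing weights; asymmetric adjacency is averaged with a logged warning.
    """
    fmt = format or _infer_format(path)
    if fmt == "adjacency-csv":
        df = pd.read_csv(path, index_col=0)
        if df.shape[0] != df.shape[1]:
            raise ValueError(
                f"{path}: adjacency not square ({df.shape[0]} rows, {df.shape[1]} columns)"
            )
        labels = [str(l) for l in df.index]
        if labels != [str(c) for c in df.columns]:
            raise ValueError(f"{path}: row labels do not match column labels")
        if len(set(labels)) != len(labels):
            raise ValueError(f"{path}: duplicate symptom labels")
        adj = df.to_numpy(dtype=float)
        if np.isnan(adj).any():
            i, j = np.argwhere(np.isnan(adj))[0]
            raise ValueError(f"{path}: NaN weight at row {labels[i]!r}, column {labels[j]!r}")
        if not np.allclose(adj, adj.T, atol=1e-10):
            log.warning("%s: asymmetric adjacency symmetrized by averaging", path)
            adj = (adj + adj.T) / 2
        np.fill_diagonal(adj, 0.0)
        return SymptomNetwork(tuple(labels), adj)
    if fmt == "edgelist-tsv":
        df = pd.read_csv(path, sep="\t", header=None, names=["source", "target", "weight"])
        if df["weight"].isna().any():
            raise ValueError(f"{path}: edge list row with missing weight")
        labels: list[str] = []
        for col in ("source", "target"):
            for v in df[col].astype(str):
                if v not in labels:
                    labels.append(v)
        edges = [
            (str(r.source), str(r.target), float(r.weight)) for r in df.itertuples()
        ]
        return SymptomNetwork.from_edges(labels, edges)
    if fmt == "graphml":
        g = nx.read_graphml(path)
        g2 = nx.Graph()
        g2.add_nodes_from(g.nodes())
        for u, v, d in g.edges(data=True):
            g2.add_edge(u, v, weight=float(d.get("weight", 1.0)))
        return SymptomNetwork.from_networkx(g2)
    raise ValueError(f"unknown format {fmt!r}")


def write_network(net: SymptomNetwork, path: str, format: Format | None = None) -> None:
    """Write a network in any supported format (inferred from extension)."""
    fmt = format or _infer_format(path)
    if fmt == "adjacency-csv":
        pd.DataFrame(net.adjacency, index=net.labels, columns=net.labels).to_csv(path)
    elif fmt == "edgelist-tsv":
        rows, cols = np.nonzero(np.triu(net.adjacency, k=1))
        with open(path, "w") as fh:
            for i, j in zip(rows, cols):
                fh.write(f"{net.labels[i]}\t{net.labels[j]}\t{float(net.adjacency[i, j])!r}\n")
    elif fmt == "graphml":
        nx.write_graphml(net.to_networkx(), path)
    else:
        raise ValueError(f"unknown format {fmt!r}")
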