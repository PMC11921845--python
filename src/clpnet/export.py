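"""Machine-readable network export/import (GraphML and TSV edge lists).

Directed cross-lagged networks export every nonzero edge with its signed
weight and a ``lag_type`` attribute (``auto`` for the self-loop i->i,
``cross`` otherwise); undirected partial-correlation networks export each
unordered pair once. Round-trips are lossless: weights are written with
full ``repr`` precision.
"""

from __future__ import annotations

import csv

import networkx as nx
import numpy as np

__all__ = ["export_network", "import_edgelist", "import_graphml"]


def _unpack(net):
    """Accept a results object (``.nodes`` + ``.A``/``.network``) or an
    (nodes, matrix, directed) triple."""
    if isinstance(net, tuple) and len(net) == 3:
        nodes, W, directed = net
        return list(nodes), np.asarray(W, dtype=float), bool(directed), None
    nodes = list(net.nodes)
    communities = getattr(net, "communities", None)
    if hasattr(net, "A"):
        return nodes, np.asarray(net.A, dtype=float), True, communities
    if hasattr(net, "network"):
        return nodes, np.asarray(net.network, dtype=float), False, communities
    raise TypeError(f"cannot export object of type {type(net).__name__}")


def export_network(net, path, format: str = "edgelist", communities: dict | None = None) -> None:
    """Write a network to ``path`` as a TSV edge list or GraphML file.

    Parameters
    ----------
    net
        A fitted network results object, or an ``(nodes, weight_matrix,
        directed)`` triple. For directed networks ``W[i, j]`` is the edge
        i -> j.
    format
        ``"edgelist"`` (TSV: source, target, weight, lag_type) or
        ``"graphml"`` (includes isolated nodes and community attributes).
    communities
        Optional node -> community mapping stored as a node attribute
        (GraphML only).
    """
    nodes, W, directed, own_comm = _unpack(net)
    communities = communities or own_comm
    if format == "edgelist":
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t")
            w.writerow(["source", "target", "weight", "lag_type"])
            for i, src in enumerate(nodes):
                cols = range(len(nodes)) if directed else range(i + 1, len(nodes))
                for j in cols:
                    if W[i, j] != 0.0:
                        lag = "auto" if i == j else "cross"
                        w.writerow([src, nodes[j], repr(float(W[i, j])), lag])
    elif format == "graphml":
        g = nx.DiGraph() if directed else nx.Graph()
        for i, node in enumerate(nodes):
            attrs = {"community": communities[node]} if communities else {}
            g.add_node(node, **attrs)
        for i in range(len(nodes)):
            cols = range(len(nodes)) if directed else range(i + 1, len(nodes))
            for j in cols:
                if W[i, j] != 0.0:
                    g.add_edge(
                        nodes[i],
                        nodes[j],
                        weight=float(W[i, j]),
                        lag_type="auto" if i == j else "cross",
                    )
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown format {format!r}; expected 'edgelist' or 'graphml'")


def import_edgelist(path, nodes) -> np.ndarray:
    """Read a TSV edge list back into a weight matrix over ``nodes``.

    The edge list does not carry isolated nodes, so the node order must be
    supplied; on matching input this inverts :func:`export_network`
    bit-exactly.
    """
    nodes = list(nodes)
    idx = {n: k for k, n in enumerate(nodes)}
    W = np.zeros((len(nodes), len(nodes)))
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            W[idx[row["source"]], idx[row["target"]]] = float(row["weight"])
    return W


def import_graphml(path):
    """Read a GraphML network; returns (nodes, weight_matrix, directed,
    communities-or-None)."""
    g = nx.read_graphml(path)
    directed = g.is_directed()
    nodes = list(g.nodes())
    idx = {n: k for k, n in enumerate(nodes)}
    W = np.zeros((len(nodes), len(nodes)))
    for u, v, data in g.edges(data=True):
        W[idx[u], idx[v]] = float(data["weight"])
        if not directed:
            W[idx[v], idx[u]] = float(data["weight"])
    comm = {n: d["community"] for n, d in g.nodes(data=True) if "community" in d}
    return nodes, W, directed, (comm or None)
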