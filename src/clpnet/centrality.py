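"""Node centrality and block-wise global characteristics of a CLPN.

Expected influence (EI) of a node is the signed sum of its incident
cross-lagged edges (incoming + outgoing; the autoregressive self-loop is
excluded). Bridge expected influence (BEI) restricts the sum to edges
whose other endpoint belongs to the *other* disorder; its z-score across
nodes is the normalized BEI used to flag bridge symptoms (normalized
BEI > 1 in every sample considered).

Block-wise global characteristics follow the two-instrument bookkeeping
of symptom-network reports: the "entire network" block counts all p^2
ordered pairs including self-loops; within-disorder blocks count ordered
pairs (with self-loops) inside the stated community; between-disorder
blocks count ordered cross pairs (no self-loops possible). Density =
nonzero / estimated and average edge weight = global strength /
estimated, where global strength is the sum of absolute weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .clpn import CLPNResults

__all__ = [
    "expected_influence",
    "bridge_expected_influence",
    "centrality_table",
    "identify_bridges",
    "global_characteristics",
    "GlobalCharacteristics",
    "top_edges",
]

BLOCKS = ("entire", "PTSD", "DEP", "PTSD->DEP", "DEP->PTSD")


def _offdiag(A: np.ndarray) -> np.ndarray:
    out = A.copy()
    np.fill_diagonal(out, 0.0)
    return out


def _resolve_communities(net: CLPNResults, communities) -> np.ndarray:
    if communities is None:
        communities = net.communities
    if communities is None:
        raise ValueError("no community labels supplied or attached to the network")
    labels = []
    for node in net.nodes:
        if node not in communities:
            raise ValueError(f"node {node!r} has no community label")
        labels.append(communities[node])
    return np.asarray(labels)


def expected_influence(net: CLPNResults, node: str | None = None, mode: str = "both"):
    """Signed sum of cross-lagged edges incident to each node.

    ``mode`` selects incoming + outgoing (default, each counted once),
    in-only, or out-only sums. Returns a pandas Series, or a float if
    ``node`` is given.
    """
    off = _offdiag(net.A)
    if mode == "both":
        ei = off.sum(axis=1) + off.sum(axis=0)
    elif mode == "out":
        ei = off.sum(axis=1)
    elif mode == "in":
        ei = off.sum(axis=0)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    s = pd.Series(ei, index=net.nodes, name="EI")
    return float(s[net.nodes[net.node_index(node)]]) if node is not None else s


def bridge_expected_influence(
    net: CLPNResults, communities: dict | None = None, node: str | None = None, mode: str = "both"
):
    """EI restricted to edges crossing the disorder boundary."""
    labels = _resolve_communities(net, communities)
    off = _offdiag(net.A)
    cross = labels[:, None] != labels[None, :]
    masked = off * cross
    if mode == "both":
        bei = masked.sum(axis=1) + masked.sum(axis=0)
    elif mode == "out":
        bei = masked.sum(axis=1)
    elif mode == "in":
        bei = masked.sum(axis=0)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    s = pd.Series(bei, index=net.nodes, name="BEI")
    return float(s[net.nodes[net.node_index(node)]]) if node is not None else s


def centrality_table(
    net: CLPNResults, communities: dict | None = None, z_threshold: float = 1.0
) -> pd.DataFrame:
    """Per-node EI, BEI, normalized (z-scored) BEI, and the single-network
    bridge flag (normalized BEI strictly greater than ``z_threshold``)."""
    ei = expected_influence(net)
    bei = bridge_expected_influence(net, communities)
    sd = bei.std(ddof=0)
    if sd == 0:
        z = pd.Series(np.zeros(len(bei)), index=bei.index)
    else:
        z = (bei - bei.mean()) / sd
    return pd.DataFrame(
        {"EI": ei, "BEI": bei, "BEI_z": z, "bridge": z > z_threshold}
    )


def identify_bridges(tables, z_threshold: float = 1.0) -> list:
    """Nodes whose normalized BEI exceeds ``z_threshold`` in *every*
    supplied centrality table (one table per sample/network)."""
    tables = list(tables)
    if not tables:
        raise ValueError("need at least one centrality table")
    base = list(tables[0].index)
    for t in tables[1:]:
        if set(t.index) != set(base):
            raise ValueError("networks have different node sets")
    flagged = [
        node
        for node in base
        if all(float(t.loc[node, "BEI_z"]) > z_threshold for t in tables)
    ]
    return flagged


@dataclass
class GlobalCharacteristics:
    """Block-wise edge counts, density, strength, and average weight."""

    table: pd.DataFrame

    def rounded(self, decimals: int = 2) -> pd.DataFrame:
        out = self.table.copy()
        out["density"] = out["density"].round(decimals)
        out["average_weight"] = out["average_weight"].round(decimals)
        return out

    def to_csv(self, path) -> None:
        self.table.to_csv(path)


def global_characteristics(
    net: CLPNResults, communities: dict[str, list] | None = None
) -> GlobalCharacteristics:
    """Compute the five-block global characteristics table.

    ``communities`` maps the two within-blocks to their item lists, e.g.
    ``{"PTSD": [...], "DEP": [...]}``; by default the PTSD block is every
    node labelled PTSD and the DEP block every node labelled DEP-NEG in
    the attached catalog-style communities (positive-affect items belong
    to neither within-block but do count in the entire network).
    """
    if communities is None:
        raise ValueError("communities mapping {block: item list} is required")
    nodes = net.nodes
    index = {n: k for k, n in enumerate(nodes)}
    for block, members in communities.items():
        unknown = set(members) - set(nodes)
        if unknown:
            raise ValueError(f"community {block!r} has items outside the network: {sorted(unknown)}")
    A = net.A
    ptsd = np.array([index[i] for i in communities["PTSD"]])
    dep = np.array([index[i] for i in communities["DEP"]])

    def stats(sub: np.ndarray, estimated: int) -> dict:
        nonzero = int((sub != 0).sum())
        strength = float(np.abs(sub).sum())
        return {
            "estimated": estimated,
            "nonzero": nonzero,
            "density": nonzero / estimated,
            "strength": strength,
            "average_weight": strength / estimated,
        }

    p = len(nodes)
    rows = {
        "entire": stats(A, p * p),
        "PTSD": stats(A[np.ix_(ptsd, ptsd)], len(ptsd) ** 2),
        "DEP": stats(A[np.ix_(dep, dep)], len(dep) ** 2),
        "PTSD->DEP": stats(A[np.ix_(ptsd, dep)], len(ptsd) * len(dep)),
        "DEP->PTSD": stats(A[np.ix_(dep, ptsd)], len(dep) * len(ptsd)),
    }
    table = pd.DataFrame.from_dict(rows, orient="index").loc[list(BLOCKS)]
    table.index.name = "block"
    return GlobalCharacteristics(table)


def top_edges(
    net: CLPNResults, block: str, communities: dict[str, list], k: int = 5, ci: dict | None = None
) -> pd.DataFrame:
    """The ``k`` largest nonzero edges by signed weight within a block.

    ``block`` is one of ``PTSD``, ``DEP``, ``PTSD->DEP``, ``DEP->PTSD``;
    autoregressive self-loops are excluded. Ties break by (source, target)
    lexical order. ``ci`` optionally maps (source, target) -> (lower,
    upper) bootstrap bounds.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if block not in ("PTSD", "DEP", "PTSD->DEP", "DEP->PTSD"):
        raise ValueError(f"unknown block {block!r}")
    index = {n: i for i, n in enumerate(net.nodes)}
    if block in ("PTSD", "DEP"):
        src_items = tgt_items = communities[block]
    else:
        a, b = block.split("->")
        src_items, tgt_items = communities[a], communities[b]
    rows = []
    for s in src_items:
        for t in tgt_items:
            if s == t:
                continue
            w = net.A[index[s], index[t]]
            if w != 0:
                rows.append({"source": s, "target": t, "weight": float(w)})
    rows.sort(key=lambda r: (-r["weight"], r["source"], r["target"]))
    out = pd.DataFrame(rows[:k], columns=["source", "target", "weight"])
    if ci is not None and len(out):
        out["ci_lower"] = [ci.get((s, t), (np.nan, np.nan))[0] for s, t in zip(out.source, out.target)]
        out["ci_upper"] = [ci.get((s, t), (np.nan, np.nan))[1] for s, t in zip(out.source, out.target)]
    return out
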