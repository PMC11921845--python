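"""Cross-sample network replicability metrics.

Two fitted cross-lagged networks over the same node catalog are compared
in four ways: (a) the Pearson correlation between their cross-lagged edge
lists (with Fisher confidence interval and t statistic), (b) the number
of edges replicated across the two networks — nonzero in both with equal
sign — together with that count as a share of each network's nonzero
cross-lagged edges (and a presence-only count ignoring sign), (c) the
Pearson correlation of the bridge-expected-influence vectors, and (d)
the overlap of the top-k nodes by normalized BEI.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .centrality import centrality_table
from .clpn import CLPNResults

__all__ = ["ReplicabilityReport", "compare_networks"]


def _fisher_ci(r: float, m: int, level: float = 0.95) -> tuple:
    if m <= 3 or abs(r) >= 1.0:
        return (np.nan, np.nan)
    z = np.arctanh(r)
    se = 1.0 / np.sqrt(m - 3)
    crit = stats.norm.ppf(0.5 + level / 2)
    return (float(np.tanh(z - crit * se)), float(np.tanh(z + crit * se)))


def _t_stat(r: float, m: int) -> float:
    if m <= 2 or abs(r) >= 1.0:
        return np.nan
    return float(r * np.sqrt(m - 2) / np.sqrt(1 - r**2))


@dataclass
class ReplicabilityReport:
    edge_r: float
    edge_r_ci: tuple
    edge_t: float
    n_edge_pairs: int
    replicated_count: int
    presence_count: int
    share_a: float
    share_b: float
    nonzero_a: int
    nonzero_b: int
    bei_r: float
    bei_r_ci: tuple
    bei_t: float
    k_top: int
    top_overlap: int
    top_a: list
    top_b: list

    def summary(self) -> str:
        lines = [
            "Network replicability",
            "=====================",
            f"edge-list Pearson r:     {self.edge_r:.3f} "
            f"[{self.edge_r_ci[0]:.3f}, {self.edge_r_ci[1]:.3f}], t = {self.edge_t:.2f} "
            f"(m = {self.n_edge_pairs} edge pairs)",
            f"replicated edges:        {self.replicated_count} same-sign "
            f"({self.presence_count} by presence)",
            f"  share of network A:    {self.share_a:.3f} (of {self.nonzero_a} nonzero)",
            f"  share of network B:    {self.share_b:.3f} (of {self.nonzero_b} nonzero)",
            f"BEI Pearson r:           {self.bei_r:.3f} "
            f"[{self.bei_r_ci[0]:.3f}, {self.bei_r_ci[1]:.3f}]",
            f"top-{self.k_top} BEI overlap:       {self.top_overlap}/{self.k_top} "
            f"(A: {self.top_a}, B: {self.top_b})",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "edge_r": self.edge_r,
            "edge_r_ci": list(self.edge_r_ci),
            "edge_t": self.edge_t,
            "n_edge_pairs": self.n_edge_pairs,
            "replicated_count": self.replicated_count,
            "presence_count": self.presence_count,
            "share_a": self.share_a,
            "share_b": self.share_b,
            "nonzero_a": self.nonzero_a,
            "nonzero_b": self.nonzero_b,
            "bei_r": self.bei_r,
            "bei_r_ci": list(self.bei_r_ci),
            "bei_t": self.bei_t,
            "k_top": self.k_top,
            "top_overlap": self.top_overlap,
            "top_a": self.top_a,
            "top_b": self.top_b,
        }


def compare_networks(
    net_a: CLPNResults,
    net_b: CLPNResults,
    communities: dict | None = None,
    k_top: int = 3,
    include_auto: bool = False,
) -> ReplicabilityReport:
    """Compare two fitted networks over identical node catalogs.

    Autoregressive edges are excluded from the edge-list correlation by
    default (``include_auto=True`` to include them); the replicated-edge
    counts always concern cross-lagged edges.
    """
    if net_a.nodes != net_b.nodes:
        raise ValueError("networks cover different node catalogs")
    p = net_a.p
    mask = np.ones((p, p), dtype=bool)
    if not include_auto:
        np.fill_diagonal(mask, False)
    va, vb = net_a.A[mask], net_b.A[mask]
    m = int(mask.sum())
    edge_r = float(np.corrcoef(va, vb)[0, 1]) if va.std() > 0 and vb.std() > 0 else np.nan

    offa, offb = net_a.A.copy(), net_b.A.copy()
    np.fill_diagonal(offa, 0.0)
    np.fill_diagonal(offb, 0.0)
    both = (offa != 0) & (offb != 0)
    presence = int(both.sum())
    replicated = int((both & (np.sign(offa) == np.sign(offb))).sum())
    nz_a, nz_b = int((offa != 0).sum()), int((offb != 0).sum())

    ta = centrality_table(net_a, communities)
    tb = centrality_table(net_b, communities)
    bei_a, bei_b = ta["BEI"].to_numpy(), tb["BEI"].to_numpy()
    bei_r = (
        float(np.corrcoef(bei_a, bei_b)[0, 1])
        if bei_a.std() > 0 and bei_b.std() > 0
        else np.nan
    )
    top_a = list(ta["BEI_z"].sort_values(ascending=False).index[:k_top])
    top_b = list(tb["BEI_z"].sort_values(ascending=False).index[:k_top])
    overlap = len(set(top_a) & set(top_b))

    return ReplicabilityReport(
        edge_r=edge_r,
        edge_r_ci=_fisher_ci(edge_r, m),
        edge_t=_t_stat(edge_r, m),
        n_edge_pairs=m,
        replicated_count=replicated,
        presence_count=presence,
        share_a=replicated / nz_a if nz_a else np.nan,
        share_b=replicated / nz_b if nz_b else np.nan,
        nonzero_a=nz_a,
        nonzero_b=nz_b,
        bei_r=bei_r,
        bei_r_ci=_fisher_ci(bei_r, p),
        bei_t=_t_stat(bei_r, p),
        k_top=k_top,
        top_overlap=overlap,
        top_a=top_a,
        top_b=top_b,
    )
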