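"""Exploratory graph analysis: EBIC graphical lasso + walktrap communities.

EGA estimates the number of latent dimensions in multivariate data by
fitting a regularized partial-correlation network (graphical lasso along
a log-spaced penalty grid, model selected by the extended BIC with
gamma = 0.5) and detecting communities with a 4-step random-walk
(walktrap) algorithm on the absolute edge weights. bootEGA repeats the
fit on subject resamples and reads the final communities from the
element-wise median network, reporting per-item replication proportions.

bootEGA applies only to cross-sectional (single-wave) data — the
procedure is undefined for directed networks, so passing a fitted
cross-lagged network raises ``TypeError``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import igraph as ig
import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.covariance import graphical_lasso
from sklearn.metrics import adjusted_rand_score

from .clpn import CLPNResults

__all__ = [
    "ebicglasso",
    "walktrap_communities",
    "ega",
    "bootega",
    "CommunitySolution",
    "community_table",
    "solution_agreement",
]


def _check_cross_sectional(data) -> np.ndarray:
    if isinstance(data, CLPNResults):
        raise TypeError(
            "EGA/bootEGA apply to cross-sectional data matrices, not to a "
            "directed cross-lagged network"
        )
    X = np.asarray(data, dtype=float)
    if X.ndim != 2:
        raise ValueError("expected an (n, p) data matrix")
    return X


def ebic(precision: np.ndarray, S: np.ndarray, n: int, gamma: float = 0.5) -> float:
    """Extended BIC of a Gaussian graphical model:
    ``-2 loglik + E log n + 4 gamma E log p`` with ``E`` the number of
    nonzero off-diagonal pairs."""
    p = S.shape[0]
    sign, logdet = np.linalg.slogdet(precision)
    if sign <= 0:
        return np.inf
    loglik = (n / 2.0) * (logdet - np.trace(S @ precision))
    E = int((np.abs(np.triu(precision, k=1)) > 1e-10).sum())
    return float(-2.0 * loglik + E * np.log(n) + 4.0 * gamma * E * np.log(p))


def ebicglasso(
    data,
    n: int | None = None,
    gamma: float = 0.5,
    n_lambda: int = 100,
    lambda_min_ratio: float = 0.01,
    tol: float = 1e-3,
    lambdas=None,
    return_details: bool = False,
):
    """EBIC-selected graphical-lasso partial-correlation network.

    ``data`` is an (n, p) matrix (a correlation matrix is also accepted if
    ``n`` is supplied). Returns the (p, p) partial-correlation matrix with
    zero diagonal; with ``return_details=True`` also the penalty grid,
    per-penalty EBIC values, and the selected penalty.
    """
    X = np.asarray(data, dtype=float)
    if X.ndim != 2:
        raise ValueError("expected a matrix")
    if X.shape[0] == X.shape[1] and np.allclose(X, X.T) and np.allclose(np.diag(X), 1.0):
        S = X.copy()
        if n is None:
            raise ValueError("sample size n is required when passing a correlation matrix")
    else:
        if np.isnan(X).any():
            raise ValueError("complete data required")
        n = X.shape[0]
        with np.errstate(invalid="raise"):
            try:
                S = np.corrcoef(X, rowvar=False)
            except FloatingPointError:
                raise ValueError("constant column; correlation undefined") from None
    p = S.shape[0]
    w = np.linalg.eigvalsh(S)
    if w.min() < -1e-8:
        S = S + (1e-4 - w.min()) * np.eye(p)
        d = np.sqrt(np.diag(S))
        S = S / np.outer(d, d)
        if np.linalg.eigvalsh(S).min() < -1e-8:
            raise ValueError("correlation matrix not positive semi-definite after repair")

    if lambdas is not None:
        grid = np.asarray(lambdas, dtype=float)
    else:
        off = np.abs(S - np.eye(p))
        lam_max = max(off.max(), 1e-3)
        grid = np.geomspace(lam_max, lam_max * lambda_min_ratio, n_lambda)
    best = (np.inf, None, None)
    ebics = np.full(len(grid), np.nan)
    for k, lam in enumerate(grid):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cov, prec = graphical_lasso(S, alpha=float(lam), max_iter=200, tol=tol)
        except (FloatingPointError, np.linalg.LinAlgError, ValueError):
            continue
        score = ebic(prec, S, n, gamma)
        ebics[k] = score
        if score < best[0]:
            best = (score, prec, lam)
    if best[1] is None:
        raise RuntimeError("graphical lasso failed to converge on the whole grid")
    prec = best[1]
    d = np.sqrt(np.diag(prec))
    pcor = -prec / np.outer(d, d)
    np.fill_diagonal(pcor, 0.0)
    pcor[np.abs(pcor) < 1e-10] = 0.0
    pcor = (pcor + pcor.T) / 2.0
    if return_details:
        return pcor, {
            "grid": grid,
            "ebic": ebics,
            "selected_lambda": best[2],
            "selected_ebic": best[0],
            "selected_precision": prec,
            "S": S,
            "n": n,
        }
    return pcor


def walktrap_communities(network: np.ndarray, steps: int = 4) -> np.ndarray:
    """Random-walk (walktrap) community assignment on absolute edge
    weights; isolated nodes get their own singleton communities. Returns
    contiguous integer labels starting at 1, ordered by first appearance."""
    W = np.abs(np.asarray(network, dtype=float))
    p = W.shape[0]
    np.fill_diagonal(W, 0.0)
    deg = W.sum(axis=0)
    isolated = deg == 0
    labels = np.zeros(p, dtype=int)
    active = np.flatnonzero(~isolated)
    if len(active):
        sub = W[np.ix_(active, active)]
        edges = [(int(a), int(b)) for a in range(len(active)) for b in range(a + 1, len(active)) if sub[a, b] > 0]
        g = ig.Graph(n=len(active), edges=edges)
        weights = [float(sub[a, b]) for a, b in edges]
        member = g.community_walktrap(weights=weights, steps=steps).as_clustering().membership
        for node, c in zip(active, member):
            labels[node] = c + 1
    next_label = labels.max() + 1 if len(active) else 1
    for node in np.flatnonzero(isolated):
        labels[node] = next_label
        next_label += 1
    # relabel contiguously by first appearance
    out = np.zeros_like(labels)
    mapping: dict[int, int] = {}
    for k, lab in enumerate(labels):
        if lab not in mapping:
            mapping[lab] = len(mapping) + 1
        out[k] = mapping[lab]
    return out


@dataclass
class CommunitySolution:
    """Per-item community assignment plus the undirected network it came
    from (single EGA fit or bootstrap-median network)."""

    items: list
    assignment: np.ndarray
    network: np.ndarray
    source: str = "single"  # or "boot-median"
    B: int | None = None
    replication: np.ndarray | None = None  # per-item stability (bootEGA)

    @property
    def n_communities(self) -> int:
        return int(self.assignment.max())

    def to_frame(self) -> pd.DataFrame:
        d = {"item": self.items, "community": self.assignment}
        if self.replication is not None:
            d["replication"] = self.replication
        return pd.DataFrame(d)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def ega(data, items=None, gamma: float = 0.5, n_lambda: int = 100, **kwargs) -> CommunitySolution:
    """Single exploratory graph analysis: EBIC-glasso network + walktrap."""
    X = _check_cross_sectional(data)
    net = ebicglasso(X, gamma=gamma, n_lambda=n_lambda, **kwargs)
    assignment = walktrap_communities(net)
    items = list(items) if items is not None else [f"x{j}" for j in range(X.shape[1])]
    return CommunitySolution(items, assignment, net, source="single")


def _match_labels(reference: np.ndarray, candidate: np.ndarray) -> np.ndarray:
    """Relabel ``candidate`` to maximise agreement with ``reference``
    (Hungarian assignment on the contingency table)."""
    ref_labels = np.unique(reference)
    cand_labels = np.unique(candidate)
    C = np.zeros((len(cand_labels), len(ref_labels)))
    for a, ca in enumerate(cand_labels):
        for b, rb in enumerate(ref_labels):
            C[a, b] = np.sum((candidate == ca) & (reference == rb))
    rows, cols = linear_sum_assignment(-C)
    mapping = {cand_labels[r]: ref_labels[c] for r, c in zip(rows, cols)}
    spare = max(int(reference.max()), int(max(mapping.values(), default=0)))
    out = np.empty_like(candidate)
    for k, lab in enumerate(candidate):
        if lab in mapping:
            out[k] = mapping[lab]
        else:
            spare += 1
            mapping[lab] = spare
            out[k] = spare
    return out


def bootega(
    data,
    items=None,
    B: int = 1000,
    seed: int = 0,
    gamma: float = 0.5,
    n_lambda: int = 100,
    return_replicates: bool = False,
    **kwargs,
) -> CommunitySolution:
    """Bootstrap EGA: communities of the element-wise median network over
    ``B`` subject-resampled EBIC-glasso fits, with per-item replication
    proportions (how often an item joins its median-network community)."""
    X = _check_cross_sectional(data)
    n, p = X.shape
    children = np.random.SeedSequence(seed).spawn(B)
    nets = []
    assigns = []
    failed = 0
    for b in range(B):
        rng = np.random.default_rng(children[b])
        rows = rng.integers(0, n, size=n)
        try:
            net_b = ebicglasso(X[rows], gamma=gamma, n_lambda=n_lambda, **kwargs)
        except (RuntimeError, ValueError):
            failed += 1
            continue
        nets.append(net_b)
        assigns.append(walktrap_communities(net_b))
    if failed > 0.05 * B:
        raise RuntimeError(f"{failed} of {B} bootEGA replicates failed")
    median_net = np.median(np.stack(nets), axis=0)
    assignment = walktrap_communities(median_net)
    hits = np.zeros(p)
    for a in assigns:
        matched = _match_labels(assignment, a)
        hits += matched == assignment
    replication = hits / len(assigns)
    items = list(items) if items is not None else [f"x{j}" for j in range(p)]
    sol = CommunitySolution(
        items, assignment, median_net, source="boot-median", B=B, replication=replication
    )
    if return_replicates:
        sol.replicate_networks = nets  # for oracle checks on the median
    return sol


def solution_agreement(a: CommunitySolution, b: CommunitySolution) -> float:
    """Adjusted Rand index between two community solutions (1 = identical
    partitions up to relabelling)."""
    if a.items != b.items:
        raise ValueError("solutions cover different item sets")
    return float(adjusted_rand_score(a.assignment, b.assignment))


def community_table(solutions: dict, catalog=None) -> pd.DataFrame:
    """Items x solutions table of community indices (one column per
    sample/wave solution), with a dysphoria flag column when a catalog is
    supplied."""
    solutions = dict(solutions)
    if not solutions:
        raise ValueError("need at least one solution")
    ref_items = None
    cols = {}
    for name, sol in solutions.items():
        if ref_items is None:
            ref_items = sol.items
        elif sol.items != ref_items:
            raise ValueError(f"solution {name!r} covers a different item set")
        cols[name] = sol.assignment
    out = pd.DataFrame(cols, index=ref_items)
    out.index.name = "item"
    if catalog is not None:
        dys = set(catalog.dysphoria_items)
        out["dysphoria"] = [i in dys for i in ref_items]
    return out
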