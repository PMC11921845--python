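"""Cross-lagged panel network (CLPN) estimation by regularized nodewise
regression.

For each symptom j, the wave-2 score is regressed on *all* wave-1 scores
with an L1 (LASSO) penalty; the penalty is chosen per node by 10-fold
cross-validation (the CV-error minimiser). Column j of the estimated
weight matrix ``A`` holds those coefficients, so ``A[i, j]`` is the effect
of item i at wave 1 on item j at wave 2 controlling for all other wave-1
items. The diagonal entries are the autoregressive self-loops; the
off-diagonal entries are the cross-lagged edges. Predictors and outcomes
are standardized to unit variance before fitting so coefficients are
comparable across nodes.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._solver import _cd_path, lambda_grid, lasso_path_gram
from .panel import PanelDataset

__all__ = ["CrossLaggedPanelModel", "CLPNResults", "fit_clpn"]


class CrossLaggedPanelModel:
    """Model object for a two-wave cross-lagged panel network.

    Parameters
    ----------
    t1, t2 : (n, p) arrays
        Complete, continuous (already transformed) wave-1 and wave-2 data.
    nodes : sequence of str, optional
        Item names (defaults to ``x0..x{p-1}``).
    cv_folds : int
        Folds for the per-node penalty cross-validation.
    lambda_rule : {"min"}
        Penalty rule; the CV-error minimiser (smallest penalty on ties).
    n_lambda, lambda_min_ratio
        Geometry of the per-node penalty grid.
    communities : dict, optional
        Node -> disorder label, carried through to the results for
        centrality and export convenience.
    """

    def __init__(
        self,
        t1,
        t2,
        nodes=None,
        cv_folds: int = 10,
        lambda_rule: str = "min",
        n_lambda: int = 100,
        lambda_min_ratio: float = 1e-3,
        tol: float = 1e-6,
        communities: dict | None = None,
    ):
        t1 = np.asarray(t1, dtype=float)
        t2 = np.asarray(t2, dtype=float)
        if t1.ndim != 2 or t1.shape != t2.shape:
            raise ValueError("t1 and t2 must be (n, p) arrays of equal shape")
        if not (np.isfinite(t1).all() and np.isfinite(t2).all()):
            raise ValueError("non-finite values in input; impute/transform first")
        n, p = t1.shape
        if n <= p:
            raise ValueError(
                f"n={n} <= p={p}: cross-validated nodewise regression needs n > p; "
                "fit with a fixed penalty instead"
            )
        if lambda_rule != "min":
            raise ValueError("only the CV-minimum lambda rule is implemented")
        self.t1, self.t2 = t1, t2
        self.nodes = list(nodes) if nodes is not None else [f"x{j}" for j in range(p)]
        if len(self.nodes) != p:
            raise ValueError("nodes length does not match data")
        self.cv_folds = int(cv_folds)
        self.lambda_rule = lambda_rule
        self.n_lambda = int(n_lambda)
        self.lambda_min_ratio = float(lambda_min_ratio)
        self.tol = float(tol)
        self.communities = dict(communities) if communities else None

    # -- construction helpers --------------------------------------------
    @classmethod
    def from_panel(
        cls,
        ds: PanelDataset,
        preprocess: bool = True,
        impute_method: str = "chained-pmm",
        seed: int = 0,
        **kwargs,
    ) -> "CrossLaggedPanelModel":
        """Build a model from an ordinal panel, optionally imputing and
        applying the nonparanormal transform (per wave)."""
        from .preprocess import impute, nonparanormal

        if preprocess:
            if not ds.is_complete():
                ds = impute(ds, method=impute_method, seed=seed)
            arr = nonparanormal(ds)
            t1, t2 = arr[:, :, 0], arr[:, :, 1]
        else:
            t1, t2 = ds.wave(0), ds.wave(1)
        communities = kwargs.pop("communities", None)
        if communities is None and ds.catalog is not None:
            communities = ds.catalog.bridging_communities()
        return cls(t1, t2, nodes=list(ds.items), communities=communities, **kwargs)

    # -- fitting ----------------------------------------------------------
    def _standardize(self):
        m1, s1 = self.t1.mean(0), self.t1.std(0, ddof=0)
        m2, s2 = self.t2.mean(0), self.t2.std(0, ddof=0)
        if (s1 == 0).any() or (s2 == 0).any():
            raise ValueError("constant column; cannot standardize")
        X = (self.t1 - m1) / s1
        Y = (self.t2 - m2) / s2
        record = {"t1_mean": m1, "t1_sd": s1, "t2_mean": m2, "t2_sd": s2}
        return X, Y, record

    def _node_rng(self, seed: int, node: str) -> np.random.Generator:
        # stream keyed by node *name* so item reordering permutes results
        return np.random.default_rng(
            np.random.SeedSequence((int(seed), zlib.crc32(node.encode())))
        )

    def fit(self, seed: int = 0, penalty="cv") -> "CLPNResults":
        """Estimate the network.

        ``penalty="cv"`` selects each node's penalty by K-fold CV;
        ``penalty="none"`` solves the unpenalized normal equations (OLS);
        a float fixes the same penalty for every node.
        """
        X, Y, record = self._standardize()
        n, p = X.shape
        A = np.zeros((p, p))

        if penalty == "none":
            A[:] = np.linalg.solve(X.T @ X, X.T @ Y)
            return self._results(A, None, None, None, seed, record, penalty="none")

        if isinstance(penalty, (int, float)) and not isinstance(penalty, bool):
            lam = float(penalty)
            if lam < 0:
                raise ValueError("penalty must be >= 0")
            for j in range(p):
                A[:, j] = lasso_path_gram(X, Y[:, j], np.array([lam]))[0]
            lam_arr = np.full(p, lam)
            return self._results(A, lam_arr, None, None, seed, record, penalty="fixed")

        if penalty != "cv":
            raise ValueError(f"unknown penalty spec {penalty!r}")

        lambdas = np.empty(p)
        grids = []
        cv_curves = []
        G_full = X.T @ X  # shared across nodes; per-fold Grams by subtraction
        Xty_full = X.T @ Y
        for j in range(p):
            y = Y[:, j]
            grid = lambda_grid(X, y, self.n_lambda, self.lambda_min_ratio)
            rng = self._node_rng(seed, self.nodes[j])
            fold_id = rng.permutation(n) % self.cv_folds
            sse = np.zeros(len(grid))
            for f in range(self.cv_folds):
                val = fold_id == f
                Xv, yv = X[val], y[val]
                G_tr = G_full - Xv.T @ Xv
                Xty_tr = Xty_full[:, j] - Xv.T @ yv
                path = _cd_path(G_tr, Xty_tr, n - len(yv), grid, self.tol, 2000)
                resid = yv[None, :] - path @ Xv.T
                sse += (resid**2).sum(axis=1)
            mse = sse / n
            # smallest lambda attaining the minimum (grid is descending)
            best = int(np.flatnonzero(mse == mse.min()).max())
            lambdas[j] = grid[best]
            full_path = _cd_path(G_full, Xty_full[:, j], n, grid, self.tol, 2000)
            A[:, j] = full_path[best]
            grids.append(grid)
            cv_curves.append(mse)
        return self._results(A, lambdas, grids, cv_curves, seed, record, penalty="cv")

    def _results(self, A, lambdas, grids, cv_curves, seed, record, penalty):
        return CLPNResults(
            nodes=list(self.nodes),
            A=A,
            lambda_per_node=lambdas,
            cv_seed=seed,
            standardization=record,
            communities=dict(self.communities) if self.communities else None,
            cv_folds=self.cv_folds if penalty == "cv" else None,
            penalty_rule=penalty,
            lambda_grids=grids,
            cv_curves=cv_curves,
            model=self,
        )


@dataclass
class CLPNResults:
    """Estimated cross-lagged panel network.

    ``A[i, j]`` is the (standardized-scale) coefficient of node i at wave
    1 predicting node j at wave 2; the diagonal holds the autoregressive
    self-loops. ``A`` is exactly sparse under the LASSO penalty.
    """

    nodes: list
    A: np.ndarray
    lambda_per_node: np.ndarray | None
    cv_seed: int | None
    standardization: dict | None
    communities: dict | None = None
    cv_folds: int | None = None
    penalty_rule: str = "cv"
    lambda_grids: list | None = field(default=None, repr=False)
    cv_curves: list | None = field(default=None, repr=False)
    model: CrossLaggedPanelModel | None = field(default=None, repr=False)

    @property
    def p(self) -> int:
        return len(self.nodes)

    def node_index(self, node: str) -> int:
        try:
            return self.nodes.index(node)
        except ValueError:
            raise KeyError(f"unknown node {node!r}") from None

    # -- edge bookkeeping -------------------------------------------------
    def split_edges(self) -> dict:
        """Partition edges into autoregressive (diagonal) and cross-lagged
        (off-diagonal) classes; class means are over nonzero edges."""
        diag = np.diag(self.A)
        off = self.A.copy()
        np.fill_diagonal(off, 0.0)
        auto = [
            (self.nodes[i], self.nodes[i], float(diag[i]))
            for i in range(self.p)
            if diag[i] != 0
        ]
        cross = [
            (self.nodes[i], self.nodes[j], float(off[i, j]))
            for i in range(self.p)
            for j in range(self.p)
            if off[i, j] != 0
        ]
        return {
            "autoregressive": auto,
            "cross_lagged": cross,
            "autoregressive_mean": float(np.mean([w for *_, w in auto])) if auto else 0.0,
            "cross_lagged_mean": float(np.mean([w for *_, w in cross])) if cross else 0.0,
        }

    def display_subnetwork(self, threshold: float = 0.05) -> "CLPNResults":
        """Copy for display: autoregressive loops removed and cross-lagged
        edges kept only when ``|w| > threshold`` (strictly greater)."""
        if threshold < 0:
            raise ValueError("threshold must be >= 0")
        A = self.A.copy()
        np.fill_diagonal(A, 0.0)
        A[np.abs(A) <= threshold] = 0.0
        return replace(self, A=A, model=None, lambda_grids=None, cv_curves=None)

    def nonzero_count(self, include_auto: bool = True) -> int:
        m = self.A != 0
        if not include_auto:
            m = m.copy()
            np.fill_diagonal(m, False)
        return int(m.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.A, index=self.nodes, columns=self.nodes)

    def summary(self) -> str:
        se = self.split_edges()
        lines = [
            "Cross-lagged panel network",
            "==========================",
            f"nodes:                 {self.p}",
            f"penalty rule:          {self.penalty_rule}"
            + (f" ({self.cv_folds}-fold CV, seed {self.cv_seed})" if self.penalty_rule == "cv" else ""),
            f"autoregressive edges:  {len(se['autoregressive'])} (mean {se['autoregressive_mean']:.3f})",
            f"cross-lagged nonzero:  {len(se['cross_lagged'])} of {self.p * (self.p - 1)}"
            f" (mean {se['cross_lagged_mean']:.3f})",
        ]
        return "\n".join(lines)


def fit_clpn(t1, t2, nodes=None, cv_folds: int = 10, seed: int = 0, **kwargs) -> CLPNResults:
    """Convenience wrapper: build a :class:`CrossLaggedPanelModel` and fit
    it with cross-validated penalties."""
    return CrossLaggedPanelModel(t1, t2, nodes=nodes, cv_folds=cv_folds, **kwargs).fit(seed=seed)
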