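"""Bootstrap accuracy and stability analysis for cross-lagged networks.

Three procedures, mirroring standard symptom-network practice:

* nonparametric (subject-resampling) bootstrap of the full network fit,
  giving percentile confidence intervals around every edge;
* case-dropping bootstrap giving the correlation-stability (CS)
  coefficient of a centrality index — the largest proportion of subjects
  that can be dropped while the subsampled index still correlates >= 0.7
  with the full-sample index in >= 95% of draws (CS > 0.25 is the usual
  minimum for interpretation, > 0.5 preferred);
* bootstrapped difference tests: a pair differs significantly when the
  percentile interval of the bootstrap difference distribution excludes
  zero (uncorrected, two-sided).

One subject resample is drawn per replicate and reused for every edge and
node; the penalty is re-selected within each replicate by the same CV
rule (set ``reselect_lambda=False`` to freeze the full-sample penalties).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .centrality import bridge_expected_influence, expected_influence
from .clpn import CrossLaggedPanelModel

__all__ = [
    "BootstrapResult",
    "StabilityResult",
    "bootstrap_edges",
    "cs_coefficient",
    "difference_tests",
    "percentile_intervals",
    "DEFAULT_CS_GRID",
]

DEFAULT_CS_GRID = tuple(np.round(np.arange(0.05, 0.751, 0.05), 2))


def _clone_model(model: CrossLaggedPanelModel, rows: np.ndarray) -> CrossLaggedPanelModel:
    return CrossLaggedPanelModel(
        model.t1[rows],
        model.t2[rows],
        nodes=model.nodes,
        cv_folds=model.cv_folds,
        n_lambda=model.n_lambda,
        lambda_min_ratio=model.lambda_min_ratio,
        tol=model.tol,
        communities=model.communities,
    )


def percentile_intervals(draws: np.ndarray, level: float = 0.95):
    """Element-wise percentile bounds over the replicate axis (axis 0).

    An element whose draws are constant (e.g. a structurally absent edge,
    zero in every replicate) gets the degenerate interval [v, v].
    """
    alpha = 1 - level
    lo = np.quantile(draws, alpha / 2, axis=0)
    hi = np.quantile(draws, 1 - alpha / 2, axis=0)
    return lo, hi


def _statistic_fn(statistic, communities):
    if callable(statistic):
        return statistic
    if statistic == "bei":
        return lambda res: bridge_expected_influence(res, communities).to_numpy()
    if statistic == "ei":
        return lambda res: expected_influence(res).to_numpy()
    raise ValueError(f"unknown statistic {statistic!r}; expected 'bei', 'ei' or a callable")


@dataclass
class BootstrapResult:
    """Edge (and centrality) draws from a nonparametric bootstrap."""

    nodes: list
    B: int
    level: float
    seed: int
    point_A: np.ndarray
    edge_draws: np.ndarray  # (B, p, p)
    bei_draws: np.ndarray | None  # (B, p)
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    n_failed: int = 0

    def point_in_interval_fraction(self) -> float:
        """Fraction of edges whose point estimate lies inside its own
        percentile interval — a sanity indicator (not guaranteed in
        theory); values well below 1 flag unstable refits."""
        inside = (self.ci_lower <= self.point_A) & (self.point_A <= self.ci_upper)
        return float(inside.mean())

    def edge_ci(self, source: str, target: str) -> tuple:
        i, j = self.nodes.index(source), self.nodes.index(target)
        return float(self.ci_lower[i, j]), float(self.ci_upper[i, j])

    def edge_ci_dict(self, nonzero_only: bool = True) -> dict:
        out = {}
        for i, s in enumerate(self.nodes):
            for j, t in enumerate(self.nodes):
                if nonzero_only and self.point_A[i, j] == 0:
                    continue
                out[(s, t)] = (float(self.ci_lower[i, j]), float(self.ci_upper[i, j]))
        return out

    def to_long_frame(self) -> pd.DataFrame:
        rows = []
        for i, s in enumerate(self.nodes):
            for j, t in enumerate(self.nodes):
                rows.append(
                    {
                        "source": s,
                        "target": t,
                        "estimate": float(self.point_A[i, j]),
                        "lower": float(self.ci_lower[i, j]),
                        "upper": float(self.ci_upper[i, j]),
                    }
                )
        return pd.DataFrame(rows)


def bootstrap_edges(
    model: CrossLaggedPanelModel,
    B: int = 1000,
    level: float = 0.95,
    seed: int = 0,
    communities: dict | None = None,
    reselect_lambda: bool = True,
    point: "CLPNResults | None" = None,
) -> BootstrapResult:
    """Percentile bootstrap of every edge (and of BEI when communities are
    available), resampling subjects with replacement."""
    if B < 100:
        raise ValueError("B must be >= 100 for percentile intervals")
    if not (0 < level < 1):
        raise ValueError("level must lie in (0, 1)")
    communities = communities or model.communities
    if point is None:
        point = model.fit(seed=seed)
    n = model.t1.shape[0]
    p = len(model.nodes)
    frozen = None if reselect_lambda else point.lambda_per_node

    draws = np.empty((B, p, p))
    bei = np.empty((B, p)) if communities else None
    children = np.random.SeedSequence(seed).spawn(B)
    failed = 0
    b_out = 0
    for b in range(B):
        rng = np.random.default_rng(children[b])
        rows = rng.integers(0, n, size=n)
        fit_seed = int(rng.integers(0, 2**31 - 1))
        try:
            m = _clone_model(model, rows)
            if frozen is None:
                res = m.fit(seed=fit_seed)
            else:
                # freeze per-node penalties from the full-sample fit
                X, Y, _ = m._standardize()
                from ._solver import lasso_path_gram

                A = np.zeros((p, p))
                for j in range(p):
                    A[:, j] = lasso_path_gram(X, Y[:, j], np.array([frozen[j]]))[0]
                res = point.__class__(
                    nodes=m.nodes, A=A, lambda_per_node=frozen, cv_seed=fit_seed,
                    standardization=None, communities=m.communities,
                )
        except (np.linalg.LinAlgError, ValueError):
            failed += 1
            continue
        draws[b_out] = res.A
        if bei is not None:
            bei[b_out] = bridge_expected_influence(res, communities).to_numpy()
        b_out += 1
    if failed > 0.05 * B:
        raise RuntimeError(f"{failed} of {B} bootstrap replicates failed to refit")
    draws = draws[:b_out]
    if bei is not None:
        bei = bei[:b_out]
    lo, hi = percentile_intervals(draws, level)
    inside = (lo <= point.A) & (point.A <= hi)
    if inside.mean() < 0.99:
        warnings.warn(
            f"point estimate outside its bootstrap interval for "
            f"{(~inside).sum()} edges; intervals may be unstable",
            RuntimeWarning,
        )
    return BootstrapResult(
        nodes=list(model.nodes),
        B=B,
        level=level,
        seed=seed,
        point_A=point.A,
        edge_draws=draws,
        bei_draws=bei,
        ci_lower=lo,
        ci_upper=hi,
        n_failed=failed,
    )


@dataclass
class StabilityResult:
    """Case-dropping bootstrap output for one centrality statistic."""

    grid: np.ndarray
    correlations: dict  # drop proportion -> array of subsample correlations
    cs: float
    r_threshold: float
    prob: float
    degenerate: bool = False

    def proportion_table(self) -> pd.DataFrame:
        rows = []
        for q in self.grid:
            c = np.asarray(self.correlations[q], dtype=float)
            ok = np.isfinite(c)
            rows.append(
                {
                    "drop_proportion": q,
                    "mean_correlation": float(c[ok].mean()) if ok.any() else np.nan,
                    "frac_above_threshold": float((c[ok] >= self.r_threshold).mean())
                    if ok.any()
                    else 0.0,
                }
            )
        return pd.DataFrame(rows)


def cs_coefficient(
    model: CrossLaggedPanelModel,
    statistic="bei",
    communities: dict | None = None,
    grid=DEFAULT_CS_GRID,
    B: int = 250,
    r_threshold: float = 0.7,
    prob: float = 0.95,
    seed: int = 0,
) -> StabilityResult:
    """Correlation-stability coefficient of a centrality statistic under
    case-dropping subsampling (without replacement)."""
    grid = np.asarray(sorted(grid), dtype=float)
    if (grid <= 0).any() or (grid >= 1).any():
        raise ValueError("drop-proportion grid must lie inside (0, 1)")
    communities = communities or model.communities
    stat = _statistic_fn(statistic, communities)
    full = stat(model.fit(seed=seed))
    if np.std(full) == 0:
        warnings.warn(
            "full-sample statistic is constant; correlation stability is undefined "
            "and reported as the maximum grid proportion",
            RuntimeWarning,
        )
        return StabilityResult(
            grid, {q: np.full(B, np.nan) for q in grid}, float(grid.max()),
            r_threshold, prob, degenerate=True,
        )
    n = model.t1.shape[0]
    children = np.random.SeedSequence(seed).spawn(len(grid))
    correlations = {}
    for qi, q in enumerate(grid):
        m_keep = int(np.ceil((1 - q) * n))
        rng = np.random.default_rng(children[qi])
        cors = np.empty(B)
        for b in range(B):
            rows = rng.choice(n, size=m_keep, replace=False)
            fit_seed = int(rng.integers(0, 2**31 - 1))
            try:
                sub = stat(_clone_model(model, rows).fit(seed=fit_seed))
                with np.errstate(invalid="ignore"):
                    cors[b] = np.corrcoef(full, sub)[0, 1]
            except (np.linalg.LinAlgError, ValueError):
                cors[b] = np.nan
        correlations[q] = cors
    cs = 0.0
    for q in grid:
        c = correlations[q]
        ok = np.isfinite(c)
        frac = (c[ok] >= r_threshold).mean() if ok.any() else 0.0
        if frac >= prob:
            cs = float(q)
    return StabilityResult(grid, correlations, cs, r_threshold, prob)


def difference_tests(
    boot: BootstrapResult,
    alpha: float = 0.05,
    which: str = "bei",
    max_elements: int = 2000,
) -> pd.DataFrame:
    """Pairwise bootstrapped difference tests.

    ``which='bei'`` compares node BEI values; ``which='edges'`` compares
    the edges that are nonzero in the point estimate. A pair is flagged
    significant when the two-sided percentile interval of the difference
    excludes zero. Returns a symmetric boolean DataFrame with an empty
    (False) diagonal; no multiple-testing correction is applied.
    """
    if boot.edge_draws.shape[0] < 100:
        raise ValueError("need >= 100 bootstrap replicates for difference tests")
    if which == "bei":
        if boot.bei_draws is None:
            raise ValueError("bootstrap was run without communities; BEI draws unavailable")
        draws = boot.bei_draws
        labels = list(boot.nodes)
    elif which == "edges":
        idx = np.argwhere(boot.point_A != 0)
        if len(idx) > max_elements:
            raise ValueError(
                f"{len(idx)} nonzero edges exceeds max_elements={max_elements}"
            )
        draws = boot.edge_draws[:, idx[:, 0], idx[:, 1]]
        labels = [f"{boot.nodes[i]}->{boot.nodes[j]}" for i, j in idx]
    else:
        raise ValueError(f"unknown which={which!r}")
    B, E = draws.shape
    sig = np.zeros((E, E), dtype=bool)
    chunk = max(1, int(2_000_000 / max(B * E, 1)))
    for start in range(0, E, chunk):
        stop = min(E, start + chunk)
        d = draws[:, start:stop, None] - draws[:, None, :]
        lo = np.quantile(d, alpha / 2, axis=0)
        hi = np.quantile(d, 1 - alpha / 2, axis=0)
        sig[start:stop] = (lo > 0) | (hi < 0)
    np.fill_diagonal(sig, False)
    sig = sig | sig.T  # enforce symmetry against interpolation asymmetries
    return pd.DataFrame(sig, index=labels, columns=labels)
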