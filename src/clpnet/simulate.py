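"""Synthetic two-wave symptom panels from a known directed ground truth.

The data-generating model is linear-Gaussian on a latent severity scale:

* wave-1 latents are multivariate normal with exchangeable correlation
  within each disorder community (and a weaker cross-disorder correlation
  for designated bridge items);
* wave-2 latents are ``z2 = W' z1 + eps`` with sparse directed weights
  ``W`` (diagonal = autoregressive self-loops, off-diagonal = cross-lagged
  effects) and independent Gaussian residuals scaled so each wave-2 latent
  has unit variance;
* both waves are discretised by per-item increasing thresholds into
  ordinal scores 0-3 (right-skewed endorsement by default), reverse-scored
  items are stored on the raw scale as ``3 - category``;
* a missing-completely-at-random mask is applied per wave.

Cross-disorder edges are placed only on designated bridge items, so the
bridge-recovery behaviour of the downstream centrality metrics is testable
against known truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .catalog import ItemCatalog
from .panel import PanelDataset

__all__ = [
    "GroundTruthNetwork",
    "SimulationConfig",
    "make_ground_truth",
    "simulate_panel",
    "simulate_cross_sectional",
]

#: Default marginal probabilities of ordinal categories 0..3 (right-skewed
#: symptom endorsement).
DEFAULT_CATEGORY_PROBS = (0.55, 0.25, 0.15, 0.05)


def default_thresholds(p: int, probs=DEFAULT_CATEGORY_PROBS) -> np.ndarray:
    """Per-item latent cut-points implied by marginal category
    probabilities under a standard-normal latent."""
    cum = np.cumsum(probs)[:-1]
    cuts = norm.ppf(cum)
    return np.tile(cuts, (p, 1))


@dataclass
class GroundTruthNetwork:
    """A known directed network generating two-wave panels.

    ``W[i, j]`` is the effect of item i at wave 1 on item j at wave 2 on
    the latent severity scale; the diagonal holds autoregressive
    coefficients. ``thresholds`` has one increasing row of 3 cut-points per
    item.
    """

    items: list
    W: np.ndarray
    sigma_e: np.ndarray
    communities: dict
    bridge_set: list
    thresholds: np.ndarray
    reverse_items: list = field(default_factory=list)
    t1_within_r: float = 0.3
    t1_bridge_r: float = 0.15
    seed: int | None = None

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        p = len(self.items)
        if self.W.shape != (p, p):
            raise ValueError(f"W shape {self.W.shape} != ({p}, {p})")
        d = np.diag(self.W)
        if (d < 0).any() or (d > 0.95).any():
            raise ValueError("autoregressive (diagonal) weights must lie in [0, 0.95]")
        if not (np.diff(self.thresholds, axis=1) > 0).all():
            raise ValueError("thresholds must be strictly increasing per item")
        missing = set(self.bridge_set) - set(self.items)
        if missing:
            raise ValueError(f"bridge items not in item list: {sorted(missing)}")

    @property
    def p(self) -> int:
        return len(self.items)

    def t1_covariance(self) -> np.ndarray:
        """Exchangeable-within-community wave-1 latent covariance; bridge
        items additionally correlate across the disorder boundary.
        Repaired to the nearest positive-definite matrix by eigenvalue
        clipping if needed."""
        p = self.p
        comm = [self.communities[i] for i in self.items]
        bridge = np.array([i in set(self.bridge_set) for i in self.items])
        S = np.eye(p)
        for a in range(p):
            for b in range(a + 1, p):
                if comm[a] == comm[b]:
                    r = self.t1_within_r
                elif bridge[a] or bridge[b]:
                    r = self.t1_bridge_r
                else:
                    r = 0.0
                S[a, b] = S[b, a] = r
        w = np.linalg.eigvalsh(S)
        if w.min() < 1e-8:
            vals, vecs = np.linalg.eigh(S)
            vals = np.clip(vals, 1e-6, None)
            S = vecs @ np.diag(vals) @ vecs.T
            d = np.sqrt(np.diag(S))
            S = S / np.outer(d, d)
        return S

    def raw_weight_matrix(self) -> np.ndarray:
        """Ground-truth weights on the *raw* (as-recorded) scale: reverse-
        scored items flip the sign of their incident edges, ``D W D`` with
        ``D = diag(+-1)``."""
        s = np.array([-1.0 if i in set(self.reverse_items) else 1.0 for i in self.items])
        return self.W * np.outer(s, s)

    def cross_lagged_mask(self) -> np.ndarray:
        m = self.W != 0
        np.fill_diagonal(m, False)
        return m

    # -- serialization ----------------------------------------------------
    def to_json(self, path) -> None:
        payload = {
            "items": self.items,
            "W": self.W.tolist(),
            "sigma_e": self.sigma_e.tolist(),
            "communities": self.communities,
            "bridge_set": list(self.bridge_set),
            "thresholds": self.thresholds.tolist(),
            "reverse_items": list(self.reverse_items),
            "t1_within_r": self.t1_within_r,
            "t1_bridge_r": self.t1_bridge_r,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "GroundTruthNetwork":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            items=d["items"],
            W=np.array(d["W"]),
            sigma_e=np.array(d["sigma_e"]),
            communities=d["communities"],
            bridge_set=d["bridge_set"],
            thresholds=np.array(d["thresholds"]),
            reverse_items=d.get("reverse_items", []),
            t1_within_r=d.get("t1_within_r", 0.3),
            t1_bridge_r=d.get("t1_bridge_r", 0.15),
            seed=d.get("seed"),
        )


@dataclass(frozen=True)
class SimulationConfig:
    """Panel-simulation settings: sample size, master seed, and per-wave
    MCAR missingness probability."""

    n: int
    seed: int
    missing_rate: float = 0.01

    def __post_init__(self) -> None:
        if self.n < 50:
            raise ValueError("n must be >= 50")
        if not (0.0 <= self.missing_rate <= 0.2):
            raise ValueError("missing_rate must lie in [0, 0.2]")
        if self.seed is None:
            raise ValueError("seed is mandatory")


def make_ground_truth(
    catalog: ItemCatalog,
    density_within: float = 0.4,
    density_between: float = 0.04,
    bridge_spec=None,
    seed: int = 0,
    auto_mean: float = 0.19,
    auto_sd: float = 0.05,
    cross_mean: float = 0.02,
    cross_sd: float = 0.01,
    bridge_weight_range: tuple = (0.13, 0.16),
    bridge_out: int = 4,
    bridge_in: int = 3,
) -> GroundTruthNetwork:
    """Draw a sparse directed ground-truth network over a catalog.

    Autoregressive weights are drawn around ``auto_mean`` (default 0.19,
    the magnitude typical of two-wave symptom panels); within-disorder
    cross-lagged weights are small and mostly positive around
    ``cross_mean``; cross-disorder edges are placed only on pairs incident
    to a bridge item (default bridge set = the dysphoria items), with
    weights in ``bridge_weight_range`` so bridges carry detectable signal.
    Every bridge item carries ``bridge_out`` guaranteed outgoing and
    ``bridge_in`` incoming cross-disorder edges whose other endpoints are
    spread evenly over the eligible receivers, so designated bridges are
    the dominant cross-disorder conduits; ``density_between`` adds further
    random cross edges incident to bridges.
    Deterministic given ``seed``.
    """
    if not (0 <= density_within < 1) or not (0 <= density_between < 1):
        raise ValueError("densities must lie in [0, 1)")
    items = catalog.item_ids
    p = len(items)
    if bridge_spec is None:
        bridge_spec = [i for i in catalog.dysphoria_items]
    missing = set(bridge_spec) - set(items)
    if missing:
        raise ValueError(f"bridge_spec items absent from catalog: {sorted(missing)}")
    comm = catalog.bridging_communities()
    rng = np.random.default_rng(seed)

    W = np.zeros((p, p))
    diag = np.clip(rng.normal(auto_mean, auto_sd, size=p), 0.0, 0.95)
    np.fill_diagonal(W, diag)

    bridge = set(bridge_spec)
    reverse = set(catalog.reverse_items)
    # cross-disorder edges avoid reverse-scored (positive-affect) endpoints:
    # the strong dysphoria<->depression links run through negative-mood items,
    # and a reverse-scored endpoint would flip the raw-scale edge sign and
    # cancel the bridge's signed influence.
    for a in range(p):
        for b in range(p):
            if a == b:
                continue
            ia, ib = items[a], items[b]
            if comm[ia] == comm[ib]:
                if rng.random() < density_within:
                    W[a, b] = rng.normal(cross_mean, cross_sd)
            else:
                if (
                    (ia in bridge or ib in bridge)
                    and ia not in reverse
                    and ib not in reverse
                    and rng.random() < density_between
                ):
                    W[a, b] = rng.uniform(*bridge_weight_range)
    # guaranteed bridge edges, receivers chosen to balance endpoint load so
    # no non-bridge item accumulates bridge-level cross influence
    load = np.zeros(p)
    for ia in bridge_spec:
        a = items.index(ia)
        others = np.array(
            [b for b in range(p) if comm[items[b]] != comm[ia] and items[b] not in reverse]
        )
        if not len(others):
            continue

        def pick(k: int) -> np.ndarray:
            shuffled = rng.permutation(others)
            order = np.argsort(load[shuffled], kind="stable")
            return shuffled[order[: min(k, len(shuffled))]]

        for b in pick(bridge_out):
            if W[a, b] == 0:
                W[a, b] = rng.uniform(*bridge_weight_range)
            load[b] += 1
        for b in pick(bridge_in):
            if W[b, a] == 0:
                W[b, a] = rng.uniform(*bridge_weight_range)
            load[b] += 1

    gt = GroundTruthNetwork(
        items=list(items),
        W=W,
        sigma_e=np.ones(p),  # placeholder, set below
        communities=comm,
        bridge_set=list(bridge_spec),
        thresholds=default_thresholds(p),
        reverse_items=list(catalog.reverse_items),
        seed=seed,
    )
    # residual sd chosen so each wave-2 latent has unit marginal variance
    S1 = gt.t1_covariance()
    explained = np.einsum("ij,ik,kj->j", W, S1, W)
    gt.sigma_e = np.sqrt(np.clip(1.0 - explained, 0.05, None))
    return gt


def simulate_panel(
    gt: GroundTruthNetwork, cfg: SimulationConfig, return_latent: bool = False
):
    """Simulate a two-wave ordinal panel from a ground-truth network.

    Returns a :class:`PanelDataset`; with ``return_latent=True`` also
    returns the continuous (n, p, 2) latent array before discretisation
    and missingness (severity scale, no reverse coding).
    """
    if not (np.diff(gt.thresholds, axis=1) > 0).all():
        raise ValueError("thresholds must be strictly increasing per item")
    rng = np.random.default_rng(cfg.seed)
    p = gt.p
    S1 = gt.t1_covariance()
    L = np.linalg.cholesky(S1)
    z1 = rng.standard_normal((cfg.n, p)) @ L.T
    eps = rng.standard_normal((cfg.n, p)) * gt.sigma_e
    z2 = z1 @ gt.W + eps

    scores = np.empty((cfg.n, p, 2))
    rev = np.array([i in set(gt.reverse_items) for i in gt.items])
    for w, z in enumerate((z1, z2)):
        cat = np.empty_like(z)
        for j in range(p):
            cat[:, j] = np.searchsorted(gt.thresholds[j], z[:, j])
        cat[:, rev] = 3.0 - cat[:, rev]
        scores[:, :, w] = cat
    if cfg.missing_rate > 0:
        mask = rng.random(scores.shape) < cfg.missing_rate
        scores[mask] = np.nan

    subjects = [f"s{k}" for k in range(cfg.n)]
    ds = PanelDataset(subjects, list(gt.items), scores)
    if return_latent:
        return ds, np.stack([z1, z2], axis=2)
    return ds


def simulate_cross_sectional(
    communities,
    within_r: float = 0.7,
    n: int = 1000,
    seed: int = 0,
    return_latent: bool = False,
):
    """One-factor-per-block cross-sectional data for community detection.

    ``communities`` is a list of block sizes. Each item loads ``within_r``
    on its block factor (pairwise within-block latent correlation =
    ``within_r**2``); blocks are independent. Latents are discretised to
    0-3 by the default thresholds.
    """
    if not (0 < within_r < 1):
        raise ValueError("within_r must lie in (0, 1)")
    sizes = list(communities)
    if any(m < 3 for m in sizes):
        raise ValueError("every block needs >= 3 items for community detection")
    p = sum(sizes)
    rng = np.random.default_rng(seed)
    z = np.empty((n, p))
    col = 0
    for k, m in enumerate(sizes):
        f = rng.standard_normal((n, 1))
        e = rng.standard_normal((n, m))
        z[:, col : col + m] = within_r * f + np.sqrt(1 - within_r**2) * e
        col += m
    cuts = default_thresholds(p)
    X = np.empty_like(z)
    for j in range(p):
        X[:, j] = np.searchsorted(cuts[j], z[:, j])
    labels = np.repeat(np.arange(1, len(sizes) + 1), sizes)
    if return_latent:
        return X, labels, z
    return X, labels
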