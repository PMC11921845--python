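import numpy as np
import pytest

from clpnet.catalog import default_catalog
from clpnet.clpn import CLPNResults
from clpnet.simulate import GroundTruthNetwork, default_thresholds


@pytest.fixture(scope="session")
def catalog33():
    return default_catalog()


@pytest.fixture
def toy_net():
    """Factory for a CLPNResults over named nodes from a weight matrix."""

    def make(A, nodes=None, communities=None):
        A = np.asarray(A, dtype=float)
        nodes = list(nodes) if nodes is not None else [f"x{j}" for j in range(A.shape[0])]
        return CLPNResults(
            nodes=nodes,
            A=A,
            lambda_per_node=None,
            cv_seed=None,
            standardization=None,
            communities=communities,
        )

    return make


def small_ground_truth(seed=0, p=6, strong=True):
    """Two 3-item communities with a known asymmetric cross-lagged
    structure; unit-variance wave-2 latents."""
    rng = np.random.default_rng(seed)
    items = [f"x{i}" for i in range(p)]
    half = p // 2
    comm = {items[i]: ("A" if i < half else "B") for i in range(p)}
    W = np.diag(rng.uniform(0.15, 0.3, p))
    if strong:
        W[0, half] = 0.25
        W[half, 1] = 0.2
        W[1, half + 1] = 0.15
        W[half + 1, 0] = 0.1
        W[2, 1] = 0.1
    gt = GroundTruthNetwork(
        items=items,
        W=W,
        sigma_e=np.ones(p),
        communities=comm,
        bridge_set=[items[0]],
        thresholds=default_thresholds(p),
    )
    S1 = gt.t1_covariance()
    explained = np.einsum("ij,ik,kj->j", W, S1, W)
    gt.sigma_e = np.sqrt(np.clip(1.0 - explained, 0.05, None))
    return gt


@pytest.fixture
def small_gt():
    return small_ground_truth
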