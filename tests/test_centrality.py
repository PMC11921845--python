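"""Expected influence, bridge metrics, global characteristics, top edges."""

import numpy as np
import pandas as pd
import pytest

from clpnet.centrality import (
    bridge_expected_influence,
    centrality_table,
    expected_influence,
    global_characteristics,
    identify_bridges,
    top_edges,
)

COMM4 = {"p1": "PTSD", "p2": "PTSD", "d1": "DEP", "d2": "DEP"}


def test_expected_influence_hand_example(toy_net):
    A = np.zeros((4, 4))
    A[0, 1] = 0.1   # out-edges of node 0
    A[0, 2] = -0.05
    A[3, 0] = 0.2   # in-edge
    net = toy_net(A, nodes=["a", "b", "c", "d"])
    assert expected_influence(net, "a") == pytest.approx(0.25)
    assert expected_influence(net, "a", mode="out") == pytest.approx(0.05)
    assert expected_influence(net, "a", mode="in") == pytest.approx(0.2)


def test_isolated_node_and_double_counting_identity(toy_net):
    rng = np.random.default_rng(0)
    A = rng.standard_normal((6, 6))
    A[:, 5] = 0.0
    A[5, :] = 0.0
    net = toy_net(A)
    ei = expected_influence(net)
    assert ei["x5"] == 0.0
    off = A.copy()
    np.fill_diagonal(off, 0.0)
    assert ei.sum() == pytest.approx(2 * off.sum())


def test_bridge_expected_influence_toy(toy_net):
    A = np.zeros((4, 4))
    A[0, 2] = 0.12  # the single PTSD -> DEP edge
    A[0, 1] = 0.5   # within-PTSD, must not count
    net = toy_net(A, nodes=list(COMM4), communities=COMM4)
    bei = bridge_expected_influence(net)
    assert bei["p1"] == pytest.approx(0.12)
    assert bei["d1"] == pytest.approx(0.12)
    assert bei["p2"] == 0.0 and bei["d2"] == 0.0


def test_bei_bounded_by_absolute_cross_mass(toy_net):
    rng = np.random.default_rng(1)
    A = rng.standard_normal((4, 4))
    net = toy_net(A, nodes=list(COMM4), communities=COMM4)
    bei = bridge_expected_influence(net)
    labels = np.array(list(COMM4.values()))
    cross = labels[:, None] != labels[None, :]
    off = A.copy()
    np.fill_diagonal(off, 0.0)
    for k, node in enumerate(COMM4):
        bound = np.abs(off[k, :][cross[k, :]]).sum() + np.abs(off[:, k][cross[:, k]]).sum()
        assert abs(bei[node]) <= bound + 1e-12


def test_unlabelled_node_errors(toy_net):
    net = toy_net(np.zeros((2, 2)), nodes=["a", "b"], communities={"a": "PTSD"})
    with pytest.raises(ValueError, match="'b'"):
        bridge_expected_influence(net)


def test_normalized_bei_is_a_zscore(toy_net):
    rng = np.random.default_rng(2)
    net = toy_net(rng.standard_normal((4, 4)), nodes=list(COMM4), communities=COMM4)
    tab = centrality_table(net)
    assert abs(tab["BEI_z"].mean()) < 1e-12
    assert tab["BEI_z"].std(ddof=0) == pytest.approx(1.0, abs=1e-12)


def _table(nodes, z):
    return pd.DataFrame({"BEI_z": z, "BEI": z, "EI": z, "bridge": [v > 1 for v in z]}, index=nodes)


def test_identify_bridges_strict_threshold_and_conjunction():
    nodes = ["a", "b", "c"]
    single = _table(nodes, [1.0, 1.5, -0.2])
    assert identify_bridges([single]) == ["b"]  # z = 1.0 exactly is not flagged
    other = _table(nodes, [1.2, 0.2, 1.3])
    assert identify_bridges([single, other]) == []  # must exceed 1 in every network
    with pytest.raises(ValueError, match="node sets"):
        identify_bridges([single, _table(["a", "b", "x"], [2, 2, 2])])
    with pytest.raises(ValueError, match="at least one"):
        identify_bridges([])


def _blocks(catalog):
    t = catalog.table
    return {
        "PTSD": t.loc[t.community == "PTSD", "item_id"].tolist(),
        "DEP": t.loc[t.community == "DEP-NEG", "item_id"].tolist(),
    }


def test_global_characteristics_counts_for_33_item_catalog(catalog33, toy_net):
    net = toy_net(np.zeros((33, 33)), nodes=catalog33.item_ids)
    gc = global_characteristics(net, _blocks(catalog33)).table
    assert gc.loc["entire", "estimated"] == 1089
    assert gc.loc["PTSD", "estimated"] == 225
    assert gc.loc["DEP", "estimated"] == 196
    assert gc.loc["PTSD->DEP", "estimated"] == 210
    assert gc.loc["DEP->PTSD", "estimated"] == 210
    assert (gc["nonzero"] == 0).all() and (gc["strength"] == 0).all()
    assert (gc["density"] == 0).all()


def test_global_characteristics_match_explicit_loop_oracle(toy_net):
    rng = np.random.default_rng(3)
    nodes = ["p1", "p2", "p3", "d1", "d2", "d3"]
    comm = {"PTSD": ["p1", "p2", "p3"], "DEP": ["d1", "d2"]}  # d3 outside both blocks
    for trial in range(5):
        A = np.where(rng.random((6, 6)) < 0.5, rng.standard_normal((6, 6)), 0.0)
        net = toy_net(A, nodes=nodes)
        gc = global_characteristics(net, comm).table

        def oracle(src, tgt):
            est = nz = 0
            strength = 0.0
            for s in src:
                for t in tgt:
                    est += 1
                    w = A[nodes.index(s), nodes.index(t)]
                    if w != 0:
                        nz += 1
                    strength += abs(w)
            return est, nz, strength

        blocks = {
            "entire": (nodes, nodes),
            "PTSD": (comm["PTSD"], comm["PTSD"]),
            "DEP": (comm["DEP"], comm["DEP"]),
            "PTSD->DEP": (comm["PTSD"], comm["DEP"]),
            "DEP->PTSD": (comm["DEP"], comm["PTSD"]),
        }
        for name, (src, tgt) in blocks.items():
            est, nz, strength = oracle(src, tgt)
            if name.endswith("->DEP") or name.endswith("->PTSD"):
                est = len(src) * len(tgt)  # ordered cross pairs, no self-loops arise
            assert gc.loc[name, "estimated"] == est
            assert gc.loc[name, "nonzero"] == nz
            assert gc.loc[name, "strength"] == pytest.approx(strength, abs=1e-12)
            assert gc.loc[name, "density"] * est == pytest.approx(nz, abs=1e-9)
            assert gc.loc[name, "average_weight"] * est == pytest.approx(strength, abs=1e-9)


def test_entire_strength_exceeds_block_sum_with_outside_items(catalog33, toy_net):
    rng = np.random.default_rng(4)
    A = rng.standard_normal((33, 33)) * (rng.random((33, 33)) < 0.3)
    net = toy_net(A, nodes=catalog33.item_ids)
    gc = global_characteristics(net, _blocks(catalog33)).table
    blocks_sum = gc.loc[["PTSD", "DEP", "PTSD->DEP", "DEP->PTSD"], "strength"].sum()
    assert gc.loc["entire", "strength"] >= blocks_sum


def test_top_edges_ranking_and_ties(toy_net):
    nodes = ["p1", "p2", "d1", "d2"]
    comm = {"PTSD": ["p1", "p2"], "DEP": ["d1", "d2"]}
    A = np.zeros((4, 4))
    A[0, 2] = 0.2
    A[0, 3] = 0.2  # tie with p1->d1: lexical order on (source, target)
    A[1, 2] = -0.1
    net = toy_net(A, nodes=nodes)
    out = top_edges(net, "PTSD->DEP", comm, k=5)
    assert len(out) == 3  # fewer nonzero edges than k
    assert list(out.source[:2]) == ["p1", "p1"]
    assert list(out.target[:2]) == ["d1", "d2"]
    assert out.weight.iloc[-1] == pytest.approx(-0.1)
    with pytest.raises(ValueError):
        top_edges(net, "PTSD->DEP", comm, k=0)
    with pytest.raises(ValueError, match="block"):
        top_edges(net, "entire", comm)


def test_top_edges_match_sort_oracle_and_exclude_self_loops(toy_net):
    rng = np.random.default_rng(5)
    nodes = [f"p{i}" for i in range(3)] + [f"d{i}" for i in range(3)]
    comm = {"PTSD": nodes[:3], "DEP": nodes[3:]}
    A = rng.standard_normal((6, 6))
    net = toy_net(A, nodes=nodes)
    out = top_edges(net, "PTSD", comm, k=4)
    pairs = [
        (s, t, A[nodes.index(s), nodes.index(t)])
        for s in comm["PTSD"]
        for t in comm["PTSD"]
        if s != t
    ]
    pairs.sort(key=lambda r: (-r[2], r[0], r[1]))
    expected = pairs[:4]
    assert list(zip(out.source, out.target)) == [(s, t) for s, t, _ in expected]
    np.testing.assert_allclose(out.weight, [w for *_, w in expected])


def test_top_edges_attaches_bootstrap_intervals(toy_net):
    nodes = ["p1", "p2", "d1", "d2"]
    comm = {"PTSD": ["p1", "p2"], "DEP": ["d1", "d2"]}
    A = np.zeros((4, 4))
    A[0, 2] = 0.2
    out = top_edges(toy_net(A, nodes=nodes), "PTSD->DEP", comm, k=1, ci={("p1", "d1"): (0.1, 0.3)})
    assert out.ci_lower.iloc[0] == 0.1 and out.ci_upper.iloc[0] == 0.3
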