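"""Item catalog, panel I/O, total scores, screening, network export."""

import numpy as np
import pandas as pd
import pytest

from clpnet.catalog import ItemCatalog, default_catalog
from clpnet.export import export_network, import_edgelist, import_graphml
from clpnet.panel import (
    PanelDataset,
    SchemaError,
    ValidationError,
    load_panel,
    save_panel,
    screen_prevalence,
    total_score,
)


# ---------------------------------------------------------------------------
# catalog
# ---------------------------------------------------------------------------

def test_default_catalog_structure(catalog33):
    assert len(catalog33) == 33
    assert len(catalog33.items_of("PTSD")) == 15
    assert len(catalog33.items_of("DEP")) == 18
    t = catalog33.table
    assert (t["community"] == "DEP-NEG").sum() == 14
    assert (t["community"] == "DEP-POS").sum() == 4
    assert set(catalog33.dysphoria_items) == {"C1", "C2", "C4", "C5", "C6", "D5"}
    assert set(catalog33.reverse_items) == {"A4", "A8", "A12", "A16"}
    # bridging communities collapse the two depression sub-communities
    assert catalog33.bridging_community("A4") == "DEP"
    assert catalog33.bridging_community("C5") == "PTSD"
    # the default catalog is a truncation of both published instruments
    assert catalog33.is_truncated("PTSD") and catalog33.is_truncated("DEP")


def test_catalog_rejects_invalid_tables(catalog33):
    t = catalog33.table.copy()
    t.loc[0, "item_id"] = t.loc[1, "item_id"]
    with pytest.raises(ValueError, match="duplicate"):
        ItemCatalog(t)
    t2 = catalog33.table.copy()
    t2.loc[t2["item_id"] == "B1", "reverse_scored"] = True
    with pytest.raises(ValueError, match="reverse_scored"):
        ItemCatalog(t2)


def test_catalog_roundtrip(tmp_path, catalog33):
    catalog33.to_csv(tmp_path / "cat.csv")
    back = ItemCatalog.from_csv(tmp_path / "cat.csv")
    pd.testing.assert_frame_equal(back.table, catalog33.table)
    catalog33.to_json(tmp_path / "cat.json")
    back2 = ItemCatalog.from_json(tmp_path / "cat.json")
    assert back2.item_ids == catalog33.item_ids


# ---------------------------------------------------------------------------
# panel loading
# ---------------------------------------------------------------------------

def _toy_csv(tmp_path, rows, items=("B1", "A6")):
    header = ["subject"] + [f"{i}_{w}" for i in items for w in ("T1", "T2")]
    lines = [",".join(header)] + [",".join(map(str, r)) for r in rows]
    path = tmp_path / "panel.csv"
    path.write_text("\n".join(lines) + "\n")
    return path


def test_load_panel_counts_missing_cells(tmp_path):
    cat = default_catalog(["B1", "A6"])
    path = _toy_csv(tmp_path, [["s1", 0, 1, 2, 3], ["s2", 1, "", 0, 2], ["s3", 3, 3, 1, 0]])
    ds = load_panel(path, cat)
    assert ds.n_subjects == 3 and ds.n_items == 2
    assert ds.missing_count() == 1
    assert ds.missing_fraction("T2") == pytest.approx(1 / 6)


def test_load_panel_schema_error_names_column(tmp_path):
    cat = default_catalog(["B1", "A6"])
    path = tmp_path / "bad.csv"
    path.write_text("subject,B1_T1,A6_T1,A6_T2\ns1,0,1,2\n")
    with pytest.raises(SchemaError, match="B1_T2"):
        load_panel(path, cat)


@pytest.mark.parametrize("bad", ["5", "-1", "2.5"])
def test_load_panel_rejects_out_of_range_values(tmp_path, bad):
    cat = default_catalog(["B1", "A6"])
    path = _toy_csv(tmp_path, [["s1", 0, 1, bad, 3]])
    with pytest.raises(ValidationError, match="row 0"):
        load_panel(path, cat)


def test_panel_save_load_roundtrip(tmp_path, catalog33):
    rng = np.random.default_rng(0)
    scores = rng.integers(0, 4, size=(20, 33, 2)).astype(float)
    scores[rng.random(scores.shape) < 0.05] = np.nan
    ds = PanelDataset([f"s{i}" for i in range(20)], catalog33.item_ids, scores, catalog=catalog33)
    save_panel(ds, tmp_path / "p.csv")
    back = load_panel(tmp_path / "p.csv", catalog33)
    np.testing.assert_array_equal(back.scores, ds.scores)
    # load -> save -> load is idempotent
    save_panel(back, tmp_path / "p2.csv")
    assert (tmp_path / "p.csv").read_text() == (tmp_path / "p2.csv").read_text()


# ---------------------------------------------------------------------------
# totals and screening
# ---------------------------------------------------------------------------

def _panel(catalog, t1_fill, t2_fill=None):
    p = len(catalog)
    scores = np.zeros((1, p, 2))
    scores[0, :, 0] = t1_fill
    scores[0, :, 1] = t1_fill if t2_fill is None else t2_fill
    return PanelDataset(["s1"], catalog.item_ids, scores, catalog=catalog)


def test_total_score_zero_and_reverse_recode(catalog33):
    ds = _panel(catalog33, 0.0)
    # reverse-scored depression items contribute 3 - 0 = 3 each
    assert total_score(ds, "PTSD", "T1")[0] == 0.0
    assert total_score(ds, "DEP", "T1")[0] == 4 * 3.0
    # recoding twice restores the original contribution
    rev = catalog33.reverse_items
    idx = [catalog33.item_ids.index(i) for i in rev]
    ds.scores[0, idx, 0] = 3.0 - ds.scores[0, idx, 0]
    ds.scores[0, idx, 0] = 3.0 - ds.scores[0, idx, 0]
    assert total_score(ds, "DEP", "T1")[0] == 12.0


def test_total_score_all_ones_ptsd_is_item_count(catalog33):
    ds = _panel(catalog33, 1.0)
    assert total_score(ds, "PTSD", "T1")[0] == 15.0


def test_total_score_invariant_under_item_permutation(catalog33):
    rng = np.random.default_rng(3)
    scores = rng.integers(0, 4, size=(5, 33, 2)).astype(float)
    ds = PanelDataset([f"s{i}" for i in range(5)], catalog33.item_ids, scores, catalog=catalog33)
    perm = rng.permutation(33)
    items_p = [catalog33.item_ids[k] for k in perm]
    ds_p = PanelDataset(
        ds.subjects, items_p, scores[:, perm, :], catalog=catalog33.subset(items_p)
    )
    for instr in ("PTSD", "DEP"):
        np.testing.assert_array_equal(
            total_score(ds, instr, "T1"), total_score(ds_p, instr, "T1")
        )


def test_total_score_missing_item_gives_missing_total(catalog33):
    ds = _panel(catalog33, 1.0)
    ds.scores[0, catalog33.item_ids.index("B1"), 0] = np.nan
    assert np.isnan(total_score(ds, "PTSD", "T1")[0])
    assert total_score(ds, "DEP", "T1")[0] == 14 + 4 * 2  # unaffected instrument


def test_screen_prevalence_inclusive_cutoff_and_denominator(catalog33):
    p = 33
    scores = np.zeros((4, p, 2))
    ptsd_idx = [catalog33.item_ids.index(i) for i in catalog33.items_of("PTSD")]
    # subject 0: PTSD total exactly 11 -> positive under the >= convention
    scores[0, ptsd_idx[:11], :] = 1.0
    # subject 1: total 10 -> negative
    scores[1, ptsd_idx[:10], :] = 1.0
    # subject 2: total 45 -> positive; subject 3: missing one PTSD item
    scores[2, ptsd_idx, :] = 3.0
    scores[3, ptsd_idx[0], :] = np.nan
    ds = PanelDataset([f"s{i}" for i in range(4)], catalog33.item_ids, scores, catalog=catalog33)
    rep = screen_prevalence(ds)
    row = rep[(rep.instrument == "PTSD") & (rep.wave == "T1")].iloc[0]
    assert row["n_scored"] == 3  # missing total excluded from the denominator
    assert row["prevalence"] == pytest.approx(2 / 3)
    assert bool(row["truncated_instrument"])


def test_screen_prevalence_zero_and_half(catalog33):
    ds = _panel(catalog33, 0.0)
    rep = screen_prevalence(ds)
    # all-zero PTSD totals are below cutoff; reverse items give DEP total 12 < 15
    assert (rep["prevalence"] == 0.0).all()
    scores = np.zeros((4, 33, 2))
    ptsd_idx = [catalog33.item_ids.index(i) for i in catalog33.items_of("PTSD")]
    scores[:2, ptsd_idx, :] = 1.0  # totals 15 >= 11 for half the subjects
    ds2 = PanelDataset([f"s{i}" for i in range(4)], catalog33.item_ids, scores, catalog=catalog33)
    rep2 = screen_prevalence(ds2)
    row = rep2[(rep2.instrument == "PTSD") & (rep2.wave == "T1")].iloc[0]
    assert row["prevalence"] == pytest.approx(0.5)


def test_screen_prevalence_all_missing_errors(catalog33):
    scores = np.full((2, 33, 2), np.nan)
    scores[:, -1, :] = 1.0  # keep the panel non-degenerate elsewhere
    scores[:, [catalog33.item_ids.index(i) for i in catalog33.items_of("DEP")], :] = 1.0
    ds = PanelDataset(["a", "b"], catalog33.item_ids, scores, catalog=catalog33)
    with pytest.raises(ValueError, match="PTSD"):
        screen_prevalence(ds)


# ---------------------------------------------------------------------------
# export / import
# ---------------------------------------------------------------------------

def test_export_roundtrip_is_lossless(tmp_path, toy_net):
    rng = np.random.default_rng(1)
    A = np.where(rng.random((5, 5)) < 0.4, rng.standard_normal((5, 5)), 0.0)
    net = toy_net(A, communities={f"x{j}": ("PTSD" if j < 3 else "DEP") for j in range(5)})
    export_network(net, tmp_path / "n.tsv", format="edgelist")
    back = import_edgelist(tmp_path / "n.tsv", net.nodes)
    np.testing.assert_array_equal(back, A)
    export_network(net, tmp_path / "n.graphml", format="graphml")
    nodes, W, directed, comm = import_graphml(tmp_path / "n.graphml")
    assert directed and nodes == net.nodes
    np.testing.assert_array_equal(W, A)
    assert comm["x0"] == "PTSD"


def test_export_empty_network_keeps_all_nodes(tmp_path, catalog33, toy_net):
    net = toy_net(np.zeros((33, 33)), nodes=catalog33.item_ids)
    export_network(net, tmp_path / "e.graphml", format="graphml")
    nodes, W, _, _ = import_graphml(tmp_path / "e.graphml")
    assert len(nodes) == 33
    assert (W == 0).all()


def test_export_edgelist_rows_and_lag_types(tmp_path, toy_net):
    A = np.zeros((3, 3))
    A[0, 1] = 0.3
    A[2, 0] = -0.1
    A[1, 1] = 0.5  # autoregressive self-loop
    export_network(toy_net(A), tmp_path / "t.tsv", format="edgelist")
    df = pd.read_csv(tmp_path / "t.tsv", sep="\t")
    assert len(df) == 3
    cross = df[df.lag_type == "cross"]
    assert len(cross) == 2
    assert set(np.sign(cross.weight)) == {1.0, -1.0}
    assert (df[df.lag_type == "auto"].source == df[df.lag_type == "auto"].target).all()
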