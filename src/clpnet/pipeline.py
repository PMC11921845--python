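"""End-to-end two-sample analysis pipeline with cached, re-runnable stages.

Stages (each writes its artifacts under ``<outdir>/<stage>/`` and is
skipped on rerun when its marker is present and no upstream stage was
recomputed):

    simulate -> preprocess -> fit -> centrality -> boot -> ega -> compare

The default configuration runs a scaled-down two-sample demonstration on
synthetic panels drawn from one shared ground-truth network, emitting the
global-characteristics, top-edge, community, and replicability tables.
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .catalog import default_catalog
from .centrality import centrality_table, global_characteristics, identify_bridges, top_edges
from .clpn import CLPNResults, CrossLaggedPanelModel
from .ega import bootega, community_table
from .export import export_network, import_edgelist
from .panel import load_panel, save_panel, screen_prevalence
from .preprocess import impute, nonparanormal, normality_screen
from .replicability import compare_networks
from .resampling import DEFAULT_CS_GRID, bootstrap_edges, cs_coefficient, difference_tests
from .simulate import SimulationConfig, make_ground_truth, simulate_panel

__all__ = ["default_config", "run_pipeline", "STAGES"]

STAGES = ("simulate", "preprocess", "fit", "centrality", "boot", "ega", "compare")


def default_config() -> dict:
    """Scaled-down two-sample demonstration configuration."""
    return {
        "seed": 0,
        "samples": {"sample_a": {"n": 600}, "sample_b": {"n": 400}},
        "simulate": {"enabled": True, "missing_rate": 0.01},
        "ground_truth": {"density_within": 0.15, "density_between": 0.06},
        "preprocess": {"impute_method": "chained-pmm"},
        "fit": {"cv_folds": 10},
        "boot": {"B": 200, "level": 0.95, "cs_B": 40, "cs_grid": [0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7]},
        "ega": {"B": 50, "samples": None, "waves": ["T1", "T2"]},
        "compare": {"k_top": 3},
    }


def _block_communities(catalog) -> dict:
    t = catalog.table
    return {
        "PTSD": t.loc[t["community"] == "PTSD", "item_id"].tolist(),
        "DEP": t.loc[t["community"] == "DEP-NEG", "item_id"].tolist(),
    }


def _load_network(fitdir: Path, name: str) -> CLPNResults:
    meta = json.loads((fitdir / f"network_{name}.json").read_text())
    A = import_edgelist(fitdir / f"network_{name}.tsv", meta["nodes"])
    return CLPNResults(
        nodes=meta["nodes"],
        A=A,
        lambda_per_node=np.array(meta["lambda_per_node"]),
        cv_seed=meta["cv_seed"],
        standardization=None,
        communities=meta["communities"],
    )


def _load_model(predir: Path, name: str, catalog, cfg) -> CrossLaggedPanelModel:
    t1 = pd.read_csv(predir / f"{name}_t1_transformed.csv").to_numpy()
    t2 = pd.read_csv(predir / f"{name}_t2_transformed.csv").to_numpy()
    return CrossLaggedPanelModel(
        t1,
        t2,
        nodes=catalog.item_ids,
        cv_folds=cfg["fit"].get("cv_folds", 10),
        communities=catalog.bridging_communities(),
    )


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(
    config: dict | None = None,
    outdir="clpnet_run",
    force: bool = False,
    upto: str | None = None,
) -> dict:
    """Execute (or resume) the pipeline; returns a summary dictionary.

    A stage is recomputed when its ``_done`` marker is missing, ``force``
    is set, or any upstream stage was recomputed; partial outputs of a
    failing stage are preserved and the failure is reported with its
    stage name. ``upto`` stops after the named stage (its prerequisites
    still run).
    """
    cfg = default_config()
    if config:
        for key, val in config.items():
            # "samples" replaces wholesale; other sections merge shallowly
            if key != "samples" and isinstance(val, dict) and isinstance(cfg.get(key), dict):
                cfg[key].update(val)
            else:
                cfg[key] = val
    upto = upto or cfg.pop("_upto", None)
    if upto is not None and upto not in STAGES:
        raise ValueError(f"unknown stage {upto!r}; expected one of {STAGES}")
    stop_at = STAGES.index(upto) if upto is not None else len(STAGES) - 1
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    catalog = default_catalog(cfg.get("items"))  # optional item subset
    seed = int(cfg["seed"])
    names = list(cfg["samples"])
    timings: dict[str, float] = {}
    recomputed: set[str] = set()
    summary: dict = {}

    def needs(stage: str, upstream: list) -> bool:
        marker = outdir / stage / "_done"
        return force or not marker.exists() or any(u in recomputed for u in upstream)

    def finish(stage: str, t0: float) -> None:
        (outdir / stage / "_done").write_text("ok\n")
        timings[stage] = round(time.time() - t0, 3)
        recomputed.add(stage)

    def run_stage(stage: str, upstream: list, fn) -> None:
        if STAGES.index(stage) > stop_at:
            return
        d = outdir / stage
        if not needs(stage, upstream):
            return
        d.mkdir(exist_ok=True)
        marker = d / "_done"
        if marker.exists():
            marker.unlink()
        t0 = time.time()
        try:
            fn(d)
        except Exception as exc:  # preserve partial outputs, name the stage
            raise PipelineError(stage, exc) from exc
        finish(stage, t0)

    # -- simulate ---------------------------------------------------------
    def do_simulate(d: Path) -> None:
        gt = make_ground_truth(catalog, seed=seed, **cfg.get("ground_truth", {}))
        gt.to_json(d / "ground_truth.json")
        for k, name in enumerate(names):
            sc = SimulationConfig(
                n=int(cfg["samples"][name]["n"]),
                seed=seed * 1000 + k + 1,
                missing_rate=float(cfg["simulate"].get("missing_rate", 0.01)),
            )
            save_panel(simulate_panel(gt, sc), d / f"{name}.csv")

    if cfg["simulate"].get("enabled", True):
        run_stage("simulate", [], do_simulate)
        panel_paths = {name: outdir / "simulate" / f"{name}.csv" for name in names}
    else:
        panel_paths = {name: Path(cfg["samples"][name]["path"]) for name in names}

    # -- preprocess -------------------------------------------------------
    def do_preprocess(d: Path) -> None:
        for name in names:
            ds = load_panel(panel_paths[name], catalog)
            screen_prevalence(ds).to_csv(d / f"{name}_prevalence.csv", index=False)
            complete = (
                ds
                if ds.is_complete()
                else impute(ds, method=cfg["preprocess"].get("impute_method", "chained-pmm"), seed=seed)
            )
            normality_screen(complete).to_csv(d / f"{name}_normality.csv")
            arr = nonparanormal(complete)
            for w, wave in enumerate(("t1", "t2")):
                pd.DataFrame(arr[:, :, w], columns=catalog.item_ids).to_csv(
                    d / f"{name}_{wave}_transformed.csv", index=False
                )

    run_stage("preprocess", ["simulate"], do_preprocess)

    # -- fit --------------------------------------------------------------
    def do_fit(d: Path) -> None:
        for name in names:
            model = _load_model(outdir / "preprocess", name, catalog, cfg)
            res = model.fit(seed=seed)
            export_network(res, d / f"network_{name}.tsv", format="edgelist")
            export_network(res, d / f"network_{name}.graphml", format="graphml")
            meta = {
                "nodes": res.nodes,
                "lambda_per_node": list(map(float, res.lambda_per_node)),
                "cv_seed": res.cv_seed,
                "cv_folds": model.cv_folds,
                "communities": res.communities,
            }
            (d / f"network_{name}.json").write_text(json.dumps(meta, indent=1))

    run_stage("fit", ["preprocess"], do_fit)
    if STAGES.index("fit") <= stop_at:
        nets = {name: _load_network(outdir / "fit", name) for name in names}
    else:
        nets = {}

    # -- centrality -------------------------------------------------------
    def do_centrality(d: Path) -> None:
        blocks = _block_communities(catalog)
        tables = []
        for name in names:
            res = nets[name]
            ct = centrality_table(res)
            ct.to_csv(d / f"{name}_centrality.csv")
            tables.append(ct)
            global_characteristics(res, blocks).table.to_csv(d / f"{name}_global.csv")
            for block in ("PTSD", "DEP", "PTSD->DEP", "DEP->PTSD"):
                safe = block.replace("->", "_to_")
                top_edges(res, block, blocks, k=5).to_csv(
                    d / f"{name}_top_edges_{safe}.csv", index=False
                )
            disp = res.display_subnetwork(0.05)
            export_network(disp, d / f"{name}_display.tsv", format="edgelist")
        bridges = identify_bridges(tables)
        (d / "bridges.json").write_text(json.dumps({"bridge_nodes": bridges}, indent=1))

    run_stage("centrality", ["fit"], do_centrality)

    # -- boot -------------------------------------------------------------
    def do_boot(d: Path) -> None:
        bcfg = cfg["boot"]
        blocks = _block_communities(catalog)
        for name in names:
            model = _load_model(outdir / "preprocess", name, catalog, cfg)
            boot = bootstrap_edges(
                model,
                B=int(bcfg.get("B", 200)),
                level=float(bcfg.get("level", 0.95)),
                seed=seed,
                point=nets[name],
            )
            boot.to_long_frame().to_csv(d / f"{name}_edge_ci.csv", index=False)
            difference_tests(boot, which="bei").to_csv(d / f"{name}_diff_bei.csv")
            ci = boot.edge_ci_dict()
            for block in ("PTSD", "DEP", "PTSD->DEP", "DEP->PTSD"):
                safe = block.replace("->", "_to_")
                top_edges(nets[name], block, blocks, k=5, ci=ci).to_csv(
                    d / f"{name}_top_edges_ci_{safe}.csv", index=False
                )
            stab = cs_coefficient(
                model,
                statistic="bei",
                grid=bcfg.get("cs_grid", list(DEFAULT_CS_GRID)),
                B=int(bcfg.get("cs_B", 40)),
                seed=seed,
            )
            (d / f"{name}_cs.json").write_text(
                json.dumps(
                    {
                        "cs_coefficient": stab.cs,
                        "r_threshold": stab.r_threshold,
                        "prob": stab.prob,
                        "table": stab.proportion_table().to_dict(orient="records"),
                    },
                    indent=1,
                )
            )

    run_stage("boot", ["preprocess", "fit"], do_boot)

    # -- ega --------------------------------------------------------------
    def do_ega(d: Path) -> None:
        ecfg = cfg["ega"]
        which = ecfg.get("samples") or names
        solutions = {}
        for name in which:
            ds = load_panel(panel_paths[name], catalog)
            complete = (
                ds if ds.is_complete() else impute(ds, seed=seed)
            )
            for w, wave in enumerate(ecfg.get("waves", ["T1", "T2"])):
                X = nonparanormal(complete.wave(wave))
                sol = bootega(
                    X, items=catalog.item_ids, B=int(ecfg.get("B", 50)), seed=seed
                )
                sol.to_csv(d / f"{name}_{wave}_communities.csv")
                export_network(
                    (sol.items, sol.network, False), d / f"{name}_{wave}_median.graphml",
                    format="graphml",
                )
                solutions[f"{name}_{wave}"] = sol
        community_table(solutions, catalog).to_csv(d / "community_table.csv")

    run_stage("ega", ["simulate", "preprocess"], do_ega)

    # -- compare ----------------------------------------------------------
    def do_compare(d: Path) -> None:
        if len(names) < 2:
            (d / "replicability.json").write_text(json.dumps({"note": "single sample"}))
            return
        a, b = names[:2]
        report = compare_networks(nets[a], nets[b], k_top=int(cfg["compare"].get("k_top", 3)))
        (d / "replicability.json").write_text(json.dumps(report.to_dict(), indent=1))
        (d / "replicability.txt").write_text(report.summary() + "\n")

    run_stage("compare", ["fit"], do_compare)

    manifest = {
        "package": "clpnet",
        "version": __version__,
        "seed": seed,
        "config": {k: v for k, v in cfg.items()},
        "stage_timings_s": timings,
        "stages_recomputed": sorted(recomputed),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))

    summary["outdir"] = str(outdir)
    summary["recomputed"] = sorted(recomputed)
    if (outdir / "compare" / "replicability.json").exists():
        summary["replicability"] = json.loads(
            (outdir / "compare" / "replicability.json").read_text()
        )
    return summary
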