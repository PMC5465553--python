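"""End-to-end orchestration: synthesize, build, analyze, record.

``run_pipeline`` executes the full analysis grid — every combination of
currency cutoff and interface set — on one synthetic scenario, writing
tidy result tables and a manifest of inputs, seeds, checksums and
per-stage runtimes.  Stages append their outputs as they complete, so a
failed run retains everything produced before the failure.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .diet_shift import AnnealingConfig, diet_shift_experiment
from .diet_stats import (
    CountMatrix,
    fit_three_state_by_diet,
    mean_layer_test,
    network_stat_contrast,
    per_node_tests,
    presence_absence,
    write_count_matrix,
)
from .distance_analysis import node_otu_correlation, pairwise_distances
from .network_build import (
    build_graph,
    export_graph_tables,
    make_interface_set,
    merge_networks,
)
from .reaction_db import add_butyrate_pseudoreaction, write_database
from .synthetic import ScenarioConfig, gen_count_matrix, gen_reaction_db


@dataclass
class RunConfig:
    scenario: ScenarioConfig = field(default_factory=ScenarioConfig)
    currency_cutoffs: tuple[int, ...] = (25, 50, 100)
    interface_sets: tuple[str, ...] = ("VFA", "VFA_AA", "ALL")
    n_rand: int = 1000
    network_stats: tuple[str, ...] = ("carbon_sum", "betweenness", "degree", "clustering")
    run_diet_shift: bool = False
    shift_iterations: int = 2000
    shift_restarts: int = 3
    out_dir: str | Path = "results"


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_all_list(db, out: Path, n_extra: int = 50) -> Path:
    """Synthetic stand-in for the larger absorbed-compound interface list."""
    generic = sorted(m for m in db.metabolites if m.startswith("M"))[:n_extra]
    path = out / "all_interface_list.txt"
    path.write_text("\n".join(generic) + "\n")
    return path


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the full grid and return the manifest (also written to disk)."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": cfg.scenario.seed,
        "stages": {},
        "outputs": {},
    }

    def stage(name: str):
        start = time.perf_counter()

        def done() -> None:
            manifest["stages"][name] = round(time.perf_counter() - start, 3)

        return done

    done = stage("synthesize")
    microbial, host = gen_reaction_db(cfg.scenario)
    host = add_butyrate_pseudoreaction(host)
    write_database(microbial, out / "db_microbial")
    write_database(host, out / "db_host")
    all_list = _write_all_list(microbial, out)
    done()

    done = stage("network_and_counts")
    merged_by: dict[tuple[int, str], object] = {}
    for cutoff in cfg.currency_cutoffs:
        mg = build_graph(microbial, cutoff)
        hg = build_graph(host, cutoff)
        for iface_name in cfg.interface_sets:
            iface = make_interface_set(
                iface_name, all_list_path=all_list if iface_name == "ALL" else None
            )
            merged = merge_networks(hg, mg, iface)
            merged_by[(cutoff, iface_name)] = merged
            export_graph_tables(merged, out / f"network_N{cutoff}_{iface_name}")
    # counts are sampled once, on the first grid cell's layered network
    first = merged_by[(cfg.currency_cutoffs[0], cfg.interface_sets[0])]
    cm, otus = gen_count_matrix(first, cfg.scenario)
    write_count_matrix(cm, out / "node_counts.tsv", out / "sample_metadata.tsv")
    otus.to_csv(out / "otu_counts.tsv", sep="\t", index_label="otu_id")
    done()

    done = stage("mean_layer_grid")
    rows = []
    for (cutoff, iface_name), merged in merged_by.items():
        result = mean_layer_test(
            cm, merged.layer, n_rand=cfg.n_rand, seed=cfg.scenario.seed
        )
        rows.append(
            {
                "interface_set": iface_name,
                "cutoff": cutoff,
                "diff_mean_layer": result.observed,
                "max_rand_diff": result.max_abs_null,
                "P": result.p_value,
            }
        )
    grid = pd.DataFrame(rows)
    grid.to_csv(out / "mean_layer_grid.tsv", sep="\t", index=False)
    done()

    done = stage("node_statistics")
    contrast_rows = []
    graph = first.microbial_graph
    for stat in cfg.network_stats:
        res = network_stat_contrast(
            cm, graph, stat, db=microbial, n_rand=cfg.n_rand, seed=cfg.scenario.seed
        )
        contrast_rows.append(
            {"statistic": stat, "diff": res.observed,
             "max_rand_diff": res.max_abs_null, "P": res.p_value}
        )
    pd.DataFrame(contrast_rows).to_csv(out / "network_stat_contrasts.tsv", sep="\t", index=False)
    per_node = per_node_tests(cm)
    per_node.to_csv(out / "per_node_tests.tsv", sep="\t")
    density = fit_three_state_by_diet(cm)
    pa = presence_absence(cm, n_rand=cfg.n_rand, seed=cfg.scenario.seed)
    with open(out / "density_and_presence.json", "w") as fh:
        json.dump(
            {
                "lrt_statistic": density["lrt_statistic"],
                "lrt_df": density["df"],
                "lrt_p": density["p_value"],
                "n_shared": pa["n_shared"],
                "n_forg_only": pa["n_forg_only"],
                "n_conc_only": pa["n_conc_only"],
            },
            fh,
            indent=2,
        )
    done()

    done = stage("distances")
    dm_nodes = pairwise_distances(cm.counts, "node")
    dm_otus = pairwise_distances(otus, "OTU")
    pair_table = dm_nodes.pair_table(cm.diets).merge(
        dm_otus.pair_table(cm.diets),
        on=["a", "b", "pair_class"],
        suffixes=("_node", "_otu"),
    )
    pair_table.to_csv(out / "pair_distances.tsv", sep="\t", index=False)
    corr = node_otu_correlation(dm_nodes, dm_otus, cm.diets)
    (out / "node_otu_correlation.json").write_text(
        json.dumps({"r": corr["r"], "n_pairs": corr["n_pairs"]}, indent=2)
    )
    done()

    if cfg.run_diet_shift:
        done = stage("diet_shift")
        shift = diet_shift_experiment(
            cm,
            graph,
            AnnealingConfig(
                iterations=cfg.shift_iterations,
                restarts=cfg.shift_restarts,
                seed=cfg.scenario.seed,
            ),
        )
        shift["pairwise"].to_csv(out / "diet_shift_pairwise.tsv", sep="\t", index=False)
        done()

    for path in sorted(out.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            manifest["outputs"][str(path.relative_to(out))] = _sha256(path)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
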