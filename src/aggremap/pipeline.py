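"""End-to-end orchestration of the two analyses, plus a synthetic demo.

``run_seeding_pipeline`` reproduces the seeding-experiment analysis: total
and phosphosite tables are preprocessed, tested for differential abundance,
thresholded into four seed lists (total up/down, phospho up/down), expanded
into four first-order PPI networks, intersected, condensed into a
stringent-confidence zero-order network, partitioned into modules and
annotated; the curated-list (RBP) overlap is extracted with its
subnetworks.  ``run_insoluble_pipeline`` is the label-free variant for the
detergent-insoluble fraction (loading-scale correction, >= fold-change
semantics, enriched-list-driven networks).  ``run_synthetic_demo`` wires the
synthetic generators to both pipelines and scores the results against the
planted truth.

Each run writes its artifacts (TSV/GMT/JSON only) under an output directory
together with a manifest of sha256 checksums; reruns with the same seed are
checksum-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from . import __version__
from .config import PipelineConfig
from .datatypes import FeatureTable, GeneSetCollection, SeedList
from .diffabund import call_significant, differential_test
from .enrichment import (
    annotate_modules,
    extract_overlap_subnetwork,
    geneset_overlap,
    hypergeometric_ora,
)
from .io_formats import (
    write_edge_table,
    write_results,
    write_seed_list,
)
from .network import (
    ModulePartition,
    NetworkResult,
    detect_modules,
    first_order_network,
    intersect_node_sets,
    write_partition,
    zero_order_network,
)
from .preprocess import preprocess_table
from .synthetic import (
    SyntheticConfig,
    generate_design,
    generate_gene_sets,
    generate_insoluble_lfq,
    generate_phospho_experiment,
    generate_ppi_network,
    generate_tmt_experiment,
)


@dataclass
class RunManifest:
    """Everything needed to audit a run: config echo, artifact checksums, counts."""

    config: dict
    artifacts: dict[str, str] = field(default_factory=dict)
    counts: dict[str, int | float] = field(default_factory=dict)
    version: str = __version__

    def add_artifact(self, outdir: Path, path: Path) -> None:
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        self.artifacts[str(path.relative_to(outdir))] = digest

    def write(self, path: Path) -> None:
        payload = {
            "version": self.version,
            "config": self.config,
            "counts": self.counts,
            "artifacts": dict(sorted(self.artifacts.items())),
        }
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


class PipelineStageError(RuntimeError):
    """A stage failed; carries the stage name and the manifest so far."""

    def __init__(self, stage: str, manifest: RunManifest, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.manifest = manifest


def _config_echo(config: PipelineConfig) -> dict:
    return {k: v for k, v in vars(config).items()}


def _write_ora(ora: pd.DataFrame, path: Path) -> None:
    ora.to_csv(path, sep="\t", index=False, float_format="%.12g")


def run_seeding_pipeline(
    protein_table: FeatureTable,
    phospho_table: FeatureTable,
    network: nx.Graph,
    gene_sets: GeneSetCollection,
    rbp_set: set[str],
    config: PipelineConfig,
    outdir: str | Path,
) -> RunManifest:
    """Full seeding analysis: preprocessing -> differential -> networks -> modules."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=_config_echo(config))
    stage = "preprocess"
    try:
        prot, prot_report = preprocess_table(protein_table, config, seed=config.seed)
        phos, phos_report = preprocess_table(phospho_table, config, seed=config.seed + 1)
        manifest.counts["proteins_in"] = protein_table.n_features
        manifest.counts["proteins_kept"] = prot.n_features
        manifest.counts["phosphosites_in"] = phospho_table.n_features
        manifest.counts["phosphosites_kept"] = phos.n_features

        stage = "differential"
        prot_res = differential_test(prot)
        phos_res = differential_test(phos)
        prot_res, total_up, total_down = call_significant(
            prot_res, config.lfc_total, config.padj, meta=prot.meta, label="total"
        )
        phos_res, phos_up, phos_down = call_significant(
            phos_res, config.lfc_phospho, config.padj, meta=phos.meta, label="phospho"
        )
        seed_lists = [total_up, total_down, phos_up, phos_down]
        for sl in seed_lists:
            manifest.counts[f"seeds_{sl.label}"] = len(sl)

        stage = "first_order_networks"
        first_orders: list[NetworkResult] = []
        for sl in seed_lists:
            if len(sl) == 0:
                first_orders.append(NetworkResult(graph=nx.Graph(), unmapped_seeds=set()))
            else:
                first_orders.append(
                    first_order_network(
                        network, sl, config.conf_cutoff, mode=config.first_order_mode
                    )
                )
            manifest.counts[f"first_order_{sl.label}_nodes"] = first_orders[-1].graph.number_of_nodes()

        stage = "intersection"
        common = intersect_node_sets(*first_orders)
        manifest.counts["intersection_nodes"] = len(common)

        stage = "zero_order"
        if common:
            zero = zero_order_network(network, common, config.conf_cutoff)
        else:
            zero = NetworkResult(graph=nx.Graph(), unmapped_seeds=set())
        manifest.counts["zero_order_nodes"] = zero.graph.number_of_nodes()
        manifest.counts["zero_order_edges"] = zero.graph.number_of_edges()

        stage = "modules"
        partition = detect_modules(zero.graph, seed=config.seed)
        manifest.counts["n_modules"] = int(partition.membership.nunique()) if len(partition.membership) else 0
        manifest.counts["modularity"] = round(partition.modularity, 6)

        stage = "module_ora"
        universe = set(zero.graph.nodes)
        module_ora = (
            annotate_modules(partition, gene_sets, universe)
            if universe
            else pd.DataFrame()
        )

        stage = "rbp_overlap"
        rbp_up, rbp_down = geneset_overlap(total_up, total_down, rbp_set)
        manifest.counts["rbp_overlap_up"] = len(rbp_up)
        manifest.counts["rbp_overlap_down"] = len(rbp_down)
        sub_up = extract_overlap_subnetwork(network, rbp_up, config.conf_cutoff)
        sub_down = extract_overlap_subnetwork(network, rbp_down, config.conf_cutoff)

        stage = "write_artifacts"
        write_results(prot_res, outdir / "total_results.tsv")
        write_results(phos_res, outdir / "phospho_results.tsv")
        prot_report.to_frame().to_csv(outdir / "total_preprocess_report.tsv", sep="\t", index=False)
        phos_report.to_frame().to_csv(outdir / "phospho_preprocess_report.tsv", sep="\t", index=False)
        for sl in seed_lists:
            write_seed_list(sl.members, outdir / f"seeds_{sl.label}.txt")
        for sl, res in zip(seed_lists, first_orders):
            write_edge_table(res.graph, outdir / f"first_order_{sl.label}.tsv")
        write_seed_list(common, outdir / "intersection_nodes.txt")
        write_edge_table(zero.graph, outdir / "zero_order.tsv")
        write_partition(partition, outdir / "modules.tsv")
        if len(module_ora):
            _write_ora(module_ora, outdir / "module_ora.tsv")
        write_seed_list(rbp_up, outdir / "rbp_overlap_up.txt")
        write_seed_list(rbp_down, outdir / "rbp_overlap_down.txt")
        write_edge_table(sub_up.graph, outdir / "rbp_subnetwork_up.tsv")
        write_edge_table(sub_down.graph, outdir / "rbp_subnetwork_down.tsv")
        for p in sorted(outdir.iterdir()):
            if p.is_file() and p.name != "manifest.json":
                manifest.add_artifact(outdir, p)
        manifest.write(outdir / "manifest.json")
    except Exception as exc:  # noqa: BLE001 - stage context is the point
        raise PipelineStageError(stage, manifest, exc) from exc
    return manifest


def run_insoluble_pipeline(
    lfq_table: FeatureTable,
    network: nx.Graph,
    gene_sets: GeneSetCollection,
    config: PipelineConfig,
    outdir: str | Path,
) -> RunManifest:
    """Label-free insoluble-fraction analysis with loading-scale correction."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=_config_echo(config))
    stage = "loading_correction"
    try:
        scales = lfq_table.design["loading_scale"].to_numpy(dtype=float)
        corrected = FeatureTable(
            lfq_table.meta,
            lfq_table.values.sub(np.log2(scales), axis=1),
            lfq_table.design,
        )

        stage = "preprocess"
        table, report = preprocess_table(corrected, config, seed=config.seed + 2)
        manifest.counts["proteins_in"] = lfq_table.n_features
        manifest.counts["proteins_kept"] = table.n_features

        stage = "differential"
        res = differential_test(table)
        res, enriched, depleted = call_significant(
            res, config.lfc_insoluble, config.padj, ge=True, meta=table.meta, label="insoluble"
        )
        manifest.counts["enriched"] = len(enriched)
        manifest.counts["depleted"] = len(depleted)

        stage = "ora"
        universe = {str(s).upper() for s in table.meta["leading_protein"]}
        ora = hypergeometric_ora(enriched.members, gene_sets, universe) if len(enriched) else pd.DataFrame()

        stage = "networks"
        if len(enriched):
            first = first_order_network(network, enriched, config.conf_cutoff, mode=config.first_order_mode)
            zero = zero_order_network(network, set(first.graph.nodes) or enriched.members, config.conf_cutoff)
        else:
            first = NetworkResult(graph=nx.Graph(), unmapped_seeds=set())
            zero = NetworkResult(graph=nx.Graph(), unmapped_seeds=set())
        manifest.counts["first_order_nodes"] = first.graph.number_of_nodes()
        manifest.counts["first_order_edges"] = first.graph.number_of_edges()

        stage = "modules"
        partition = detect_modules(zero.graph, seed=config.seed)
        manifest.counts["n_modules"] = int(partition.membership.nunique()) if len(partition.membership) else 0

        stage = "write_artifacts"
        write_results(res, outdir / "insoluble_results.tsv")
        report.to_frame().to_csv(outdir / "insoluble_preprocess_report.tsv", sep="\t", index=False)
        write_seed_list(enriched.members, outdir / "insoluble_enriched.txt")
        if len(ora):
            _write_ora(ora, outdir / "insoluble_ora.tsv")
        write_edge_table(first.graph, outdir / "insoluble_first_order.tsv")
        write_edge_table(zero.graph, outdir / "insoluble_zero_order.tsv")
        write_partition(partition, outdir / "insoluble_modules.tsv")
        for p in sorted(outdir.iterdir()):
            if p.is_file() and p.name != "manifest.json":
                manifest.add_artifact(outdir, p)
        manifest.write(outdir / "manifest.json")
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError(stage, manifest, exc) from exc
    return manifest


# ---------------------------------------------------------------------------
# Synthetic demo


def _sub_seeds(seed: int, n: int) -> list[int]:
    state = np.random.SeedSequence(seed).generate_state(n)
    return [int(s) & 0x7FFFFFFF for s in state]


def _demo_inputs(config: PipelineConfig) -> dict:
    """Build the full synthetic study: PPI graph, TMT + phospho + LFQ tables.

    Three 20-node planted modules supply the seed genes: within each module
    the first four blocks of five nodes are planted as total-up, total-down,
    phospho-up and phospho-down respectively, so the four first-order
    networks all cover the module nodes and their intersection recovers the
    planted community structure.
    """
    s = _sub_seeds(config.seed, 8)
    graph, net_truth = generate_ppi_network(
        n_nodes=60, n_modules=3, p_within=0.5, p_between=0.02,
        conf_within=0.9995, conf_between=0.8, seed=s[0],
    )
    modules = net_truth.module_id
    blocks: dict[str, list[str]] = {"total_up": [], "total_down": [], "phospho_up": [], "phospho_down": []}
    for mid in sorted(modules.unique()):
        nodes = sorted(modules.index[modules == mid])
        blocks["total_up"] += nodes[0:5]
        blocks["total_down"] += nodes[5:10]
        blocks["phospho_up"] += nodes[10:15]
        blocks["phospho_down"] += nodes[15:20]

    design = generate_design(5, "day14", seed=s[1])

    # total proteome: network genes first, then background proteins
    n_total = 2000
    total_symbols = list(modules.index) + [f"TP{i:05d}" for i in range(n_total - 60)]
    de_signs = {g: +1 for g in blocks["total_up"]}
    de_signs.update({g: -1 for g in blocks["total_down"]})
    rng = np.random.default_rng(s[2])
    background = rng.choice(total_symbols[60:], size=240, replace=False)
    for i, g in enumerate(background):
        de_signs[g] = +1 if i < 120 else -1
    total_cfg = SyntheticConfig(
        n_features=n_total, n_per_group=5, lfc_magnitude=1.0, noise_sd=0.25,
        censor_quantile=0.03, mar_rate=0.01, seed=s[3],
    )
    total_table, total_truth = generate_tmt_experiment(
        total_cfg, design, feature_symbols=total_symbols, de_signs=de_signs
    )

    # phosphoproteome: 3 sites per protein, larger planted effects
    n_sites = 1200
    phos_prots = list(modules.index) + [f"PH{i:05d}" for i in range(n_sites // 3 - 60)]
    site_ids = lambda p: [f"{p}_{17 + 10 * k}" for k in range(3)]  # noqa: E731
    phos_signs: dict[str, int] = {}
    for g in blocks["phospho_up"]:
        phos_signs.update({sid: +1 for sid in site_ids(g)})
    for g in blocks["phospho_down"]:
        phos_signs.update({sid: -1 for sid in site_ids(g)})
    bg_prots = rng.choice(phos_prots[60:], size=40, replace=False)
    for i, g in enumerate(bg_prots):
        for sid in site_ids(g):
            phos_signs[sid] = +1 if i < 20 else -1
    phos_cfg = SyntheticConfig(
        n_features=n_sites, n_per_group=5, lfc_magnitude=2.0, noise_sd=0.25,
        censor_quantile=0.03, mar_rate=0.01, seed=s[4],
    )
    phos_table, phos_truth = generate_phospho_experiment(
        phos_cfg, design, sites_per_protein=3, protein_symbols=phos_prots, de_signs=phos_signs
    )

    # label-free insoluble fraction: up-only enrichment, loading differences
    lfq_design = generate_design(5, "day21", seed=s[5], pooled=False)
    lfq_symbols = list(modules.index) + [f"IN{i:05d}" for i in range(800 - 60)]
    lfq_signs = {g: +1 for g in blocks["total_up"]}
    lfq_bg = rng.choice(lfq_symbols[60:], size=45, replace=False)
    lfq_signs.update({g: +1 for g in lfq_bg})
    lfq_cfg = SyntheticConfig(
        n_features=800, n_per_group=5, lfc_magnitude=1.0, noise_sd=0.25,
        censor_quantile=0.03, mar_rate=0.01, seed=s[6],
    )
    scales = np.random.default_rng(s[7]).uniform(0.7, 1.4, size=len(lfq_design))
    lfq_table, lfq_truth = generate_insoluble_lfq(
        lfq_cfg, lfq_design, list(scales), feature_symbols=lfq_symbols, de_signs=lfq_signs
    )

    gene_sets = generate_gene_sets(net_truth, n_extra_sets=5, seed=s[2])
    rbp_set = set(rng.choice(total_symbols, size=300, replace=False)) | set(blocks["total_up"][:8])

    return {
        "graph": graph,
        "net_truth": net_truth,
        "design": design,
        "total_table": total_table,
        "total_truth": total_truth,
        "phospho_table": phos_table,
        "phospho_truth": phos_truth,
        "lfq_table": lfq_table,
        "lfq_truth": lfq_truth,
        "gene_sets": gene_sets,
        "rbp_set": rbp_set,
    }


def _recall_fdr(results: pd.DataFrame, truth) -> tuple[float, float]:
    """Directional recall over all planted DE features, and FDR among calls."""
    lfc = truth.true_log2fc
    planted = lfc[lfc != 0]
    called = results[results["call"] != "ns"]
    correct = 0
    for fid, true_fc in planted.items():
        if fid in called.index:
            call = called.loc[fid, "call"]
            if (true_fc > 0 and call == "up") or (true_fc < 0 and call == "down"):
                correct += 1
    recall = correct / len(planted) if len(planted) else float("nan")
    false_calls = sum(1 for fid in called.index if lfc.get(fid, 0.0) == 0.0)
    fdr = false_calls / len(called) if len(called) else 0.0
    return recall, fdr


def run_synthetic_demo(config: PipelineConfig, outdir: str | Path) -> tuple[RunManifest, dict]:
    """Generate synthetic inputs, run both pipelines, score against truth.

    Returns the seeding-run manifest and a scorecard dict (DE recall and
    FDR per table, module adjusted Rand index, ORA top-hit accuracy,
    insoluble recall, intersection size).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    inputs = _demo_inputs(config)

    manifest = run_seeding_pipeline(
        inputs["total_table"],
        inputs["phospho_table"],
        inputs["graph"],
        inputs["gene_sets"],
        inputs["rbp_set"],
        config,
        outdir / "seeding",
    )
    insol_manifest = run_insoluble_pipeline(
        inputs["lfq_table"],
        inputs["graph"],
        inputs["gene_sets"],
        config,
        outdir / "insoluble",
    )

    total_res = pd.read_csv(outdir / "seeding" / "total_results.tsv", sep="\t", index_col=0)
    phos_res = pd.read_csv(outdir / "seeding" / "phospho_results.tsv", sep="\t", index_col=0)
    insol_res = pd.read_csv(outdir / "insoluble" / "insoluble_results.tsv", sep="\t", index_col=0)

    recall_t, fdr_t = _recall_fdr(total_res, inputs["total_truth"])
    recall_p, fdr_p = _recall_fdr(phos_res, inputs["phospho_truth"])
    recall_i, fdr_i = _recall_fdr(insol_res, inputs["lfq_truth"])

    membership = pd.read_csv(outdir / "seeding" / "modules.tsv", sep="\t", index_col=0)["module_id"]
    truth_modules = inputs["net_truth"].module_id
    shared = [n for n in membership.index if n in truth_modules.index]
    ari = (
        adjusted_rand_score(truth_modules.loc[shared], membership.loc[shared])
        if len(shared) >= 2
        else float("nan")
    )

    ora_path = outdir / "seeding" / "module_ora.tsv"
    top_hit_acc = float("nan")
    if ora_path.exists():
        ora = pd.read_csv(ora_path, sep="\t")
        detected = ModulePartition(membership=membership, modularity=0.0).modules()
        scored, hits = 0, 0
        for mid, members in detected.items():
            members = [m for m in members if m in truth_modules.index]
            if len(members) < 3:
                continue
            true_label = int(truth_modules.loc[members].mode().iloc[0])
            top = ora[(ora["module_id"] == mid) & ora["top_hit"]]
            if len(top):
                scored += 1
                if top["set_name"].iloc[0] == f"module_{true_label:02d}":
                    hits += 1
        top_hit_acc = hits / scored if scored else float("nan")

    scorecard = {
        "de_recall_total": recall_t,
        "de_fdr_total": fdr_t,
        "de_recall_phospho": recall_p,
        "de_fdr_phospho": fdr_p,
        "insoluble_recall": recall_i,
        "insoluble_fdr": fdr_i,
        "module_ari": ari,
        "ora_top_hit_accuracy": top_hit_acc,
        "intersection_nodes": manifest.counts["intersection_nodes"],
        "insoluble_enriched": insol_manifest.counts["enriched"],
    }
    (outdir / "scorecard.json").write_text(json.dumps(scorecard, indent=2, sort_keys=True) + "\n")
    return manifest, scorecard
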