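"""End-to-end orchestration: simulate/load → score → subnetworks → overlaps →
Global Network → enrichment, with a machine-readable run manifest.

Every stage writes its outputs under the configured ``out_dir`` and the
manifest records parameters and a sha256 checksum per file; two runs with
the same configuration and seed produce byte-identical trees.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig
from .enrichment import EnrichmentResult, enrich_three_settings
from .global_network import (
    GlobalNetwork,
    TopologySummary,
    central_union,
    classify_interactors,
    compute_centralities,
    crosstalk_scores,
    delta_distribution,
    filter_by_delta,
    merge_networks,
    select_central,
    summarize_topology,
    write_global_network,
)
from .io import (
    SeedSet,
    filter_phenotypes_by_seed_count,
    read_category_map,
    read_edge_list,
    read_gmt,
    read_seed_file,
)
from .overlap import OverlapNetwork, all_pairwise_overlaps, top_candidates
from .propagation import ScoreTable, null_ensemble, score_phenotype
from .subnetwork import (
    PhenotypeNetwork,
    build_phenotype_network,
    write_phenotype_network,
)
from .synthetic import (
    SyntheticTruth,
    generate_fixture,
    synthetic_gene_sets,
    write_fixture_bundle,
)

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name is part of the message."""


def write_score_table(
    table: ScoreTable, seed_set: SeedSet, path: str | Path
) -> None:
    """Write a score table as TSV (protein, score, is_seed) with a header
    comment carrying phenotype, category and algorithm."""
    path = Path(path)
    with path.open("w") as handle:
        handle.write(
            f"#phenotype_id={table.phenotype_id}\tcategory={seed_set.category}"
            f"\talgorithm={table.algorithm}\n"
        )
        handle.write("protein\tscore\tis_seed\n")
        for protein in sorted(table.scores):
            is_seed = int(protein in seed_set.seeds)
            handle.write(f"{protein}\t{table.scores[protein]:.12g}\t{is_seed}\n")


def read_score_table(path: str | Path) -> tuple[ScoreTable, SeedSet]:
    """Read a TSV written by :func:`write_score_table`."""
    path = Path(path)
    with path.open() as handle:
        header = handle.readline().strip()
        if not header.startswith("#"):
            raise ValueError(f"{path}: missing metadata header")
        meta = dict(
            item.split("=", 1) for item in header.lstrip("#").split("\t")
        )
        handle.readline()  # column header
        scores: dict[str, float] = {}
        seeds: set[str] = set()
        for line in handle:
            protein, score, is_seed = line.rstrip("\n").split("\t")
            scores[protein] = float(score)
            if is_seed == "1":
                seeds.add(protein)
    table = ScoreTable(meta["phenotype_id"], meta["algorithm"], scores)
    seed_set = SeedSet(meta["phenotype_id"], meta["category"], frozenset(seeds))
    return table, seed_set


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    digest.update(path.read_bytes())
    return digest.hexdigest()


@dataclass
class PipelineResult:
    """In-memory results plus the manifest of one pipeline run."""

    manifest: dict
    interactome: nx.Graph
    seed_sets: list[SeedSet]
    truth: SyntheticTruth | None
    score_tables: dict[str, ScoreTable]
    networks: list[PhenotypeNetwork]
    overlaps: list[OverlapNetwork]
    global_network: GlobalNetwork
    crosstalk: pd.DataFrame
    central_selection: dict[str, dict[str, list[str]]]
    central_proteins: set[str]
    refined_proteins: set[str]
    interactor_classes: dict[str, str]
    topology: TopologySummary
    delta_summary: dict
    enrichment: dict[str, list[EnrichmentResult]] | None


def _write_candidates(
    overlap: OverlapNetwork, k: int, path: Path
) -> None:
    with path.open("w") as handle:
        handle.write("protein\toverlap_score\trole_1\trole_2\n")
        for protein, score, role_1, role_2 in top_candidates(overlap, k):
            handle.write(f"{protein}\t{score:.12g}\t{role_1}\t{role_2}\n")


def global_stage(
    networks: Sequence[PhenotypeNetwork],
    score_tables: Mapping[str, ScoreTable],
    category_map: Mapping[str, str],
    delta_threshold: float = 0.1,
    top_k: int = 5,
) -> dict[str, Any]:
    """Merged-network analysis shared by the pipeline and the CLI.

    Merges the phenotype networks, annotates centralities, computes the dual
    crosstalk scores over the merged node set, selects the top-k central
    proteins of the stress-related category groups, refines them by the
    dual-score shift, classifies their interactors and summarizes topology.
    """
    global_net = compute_centralities(merge_networks(list(networks), category_map))
    scores = crosstalk_scores(
        list(score_tables.values()), category_map, global_net.nodes
    )
    selection = select_central(global_net, k=top_k, restrict="os_related")
    centrals = central_union(selection)
    refined = filter_by_delta(scores, centrals, threshold=delta_threshold)
    classes = classify_interactors(global_net, centrals)
    topology = summarize_topology(global_net)
    return {
        "global_network": global_net,
        "crosstalk": scores,
        "selection": selection,
        "centrals": centrals,
        "refined": refined,
        "interactor_classes": classes,
        "topology": topology,
        "delta_summary": delta_distribution(scores, threshold=delta_threshold),
    }


def _stage(name: str):
    def decorator(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raised with context
                raise StageError(f"stage {name!r} failed: {exc}") from exc
        return wrapped
    return decorator


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full pipeline described by ``config``.

    Stages run in order (inputs, propagation, subnetworks, overlaps, global,
    enrichment); a failure anywhere aborts with a stage-named error. All
    randomness derives from ``config.rng_seed``.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.rng_seed)
    fixture_seed, propagation_seed, geneset_seed = (
        int(s) for s in rng.integers(0, 2**31 - 1, size=3)
    )
    outputs: dict[str, str] = {}

    @_stage("inputs")
    def load_inputs():
        truth = None
        gene_sets = None
        if config.synthetic is not None:
            syn = config.synthetic
            graph, seed_sets, truth = generate_fixture(
                fixture_seed,
                n_nodes=syn.n_nodes,
                attach_m=syn.attach_m,
                specs=syn.specs(),
                module_density=syn.module_density,
                seed_fraction=syn.seed_fraction,
                inter_category_overlap=syn.inter_category_overlap,
                n_bridges=syn.n_bridges,
            )
            gene_sets = synthetic_gene_sets(
                truth, graph, geneset_seed,
                n_random_sets=syn.n_decoy_sets,
                random_set_size=syn.decoy_set_size,
            )
            fixture_paths = write_fixture_bundle(
                truth, graph, seed_sets, out_dir / "fixture", gene_sets=gene_sets
            )
            outputs.update(
                {f"fixture/{k}": str(v) for k, v in fixture_paths.items()}
            )
        else:
            graph = read_edge_list(config.inputs.edges)
            category_map = read_category_map(config.inputs.categories)
            seed_sets = read_seed_file(config.inputs.seeds, graph, category_map)
            if config.inputs.gene_sets is not None:
                gene_sets = read_gmt(config.inputs.gene_sets)
        seed_sets = filter_phenotypes_by_seed_count(seed_sets, config.min_seeds)
        if not seed_sets:
            raise ValueError("no phenotype passed the seed-count filter")
        return graph, seed_sets, truth, gene_sets

    graph, seed_sets, truth, gene_sets = load_inputs()
    category_map = {s.phenotype_id: s.category for s in seed_sets}

    @_stage("propagation")
    def propagate():
        params = config.propagation_params(propagation_seed)
        nulls = null_ensemble(graph, params)
        scores_dir = out_dir / "scores"
        scores_dir.mkdir(exist_ok=True)
        tables: dict[str, ScoreTable] = {}
        for seed_set in seed_sets:
            logger.info("scoring phenotype %s", seed_set.phenotype_id)
            table = score_phenotype(graph, seed_set, params, null_graphs=nulls)
            tables[seed_set.phenotype_id] = table
            path = scores_dir / f"{seed_set.phenotype_id}.tsv"
            write_score_table(table, seed_set, path)
            outputs[f"scores/{seed_set.phenotype_id}"] = str(path)
        return tables

    score_tables = propagate()

    @_stage("subnetworks")
    def extract_networks():
        nets_dir = out_dir / "networks"
        nets_dir.mkdir(exist_ok=True)
        networks = []
        for seed_set in seed_sets:
            network = build_phenotype_network(
                graph,
                score_tables[seed_set.phenotype_id],
                seed_set,
                fraction=config.fraction,
                max_linkers=config.max_linkers,
            )
            networks.append(network)
            path = nets_dir / f"{seed_set.phenotype_id}.graphml"
            write_phenotype_network(network, path)
            outputs[f"networks/{seed_set.phenotype_id}"] = str(path)
        return networks

    networks = extract_networks()

    @_stage("overlaps")
    def build_overlaps():
        overlaps = all_pairwise_overlaps(
            networks, pairing=config.pairing, edge_mode=config.edge_mode
        )
        overlap_dir = out_dir / "overlap"
        overlap_dir.mkdir(exist_ok=True)
        for overlap in overlaps:
            stem = f"{overlap.pair[0]}__{overlap.pair[1]}"
            path = overlap_dir / f"{stem}.tsv"
            _write_candidates(overlap, config.n_top_candidates, path)
            outputs[f"overlap/{stem}"] = str(path)
        return overlaps

    overlaps = build_overlaps()

    @_stage("global")
    def analyze_global():
        results = global_stage(
            networks,
            score_tables,
            category_map,
            delta_threshold=config.delta_threshold,
            top_k=config.top_k,
        )
        global_dir = out_dir / "global"
        global_dir.mkdir(exist_ok=True)
        graphml_path = global_dir / "global.graphml"
        write_global_network(results["global_network"], graphml_path)
        outputs["global/graphml"] = str(graphml_path)

        scores_path = global_dir / "crosstalk_scores.tsv"
        results["crosstalk"].round(12).to_csv(scores_path, sep="\t")
        outputs["global/crosstalk_scores"] = str(scores_path)

        centrals_path = global_dir / "central_proteins.tsv"
        with centrals_path.open("w") as handle:
            handle.write("category_label\tmeasure\trank\tprotein\trefined\n")
            for label in sorted(results["selection"]):
                for measure in ("degree", "betweenness"):
                    for rank, protein in enumerate(
                        results["selection"][label][measure], start=1
                    ):
                        refined = int(protein in results["refined"])
                        handle.write(
                            f"{label}\t{measure}\t{rank}\t{protein}\t{refined}\n"
                        )
        outputs["global/central_proteins"] = str(centrals_path)

        interactors_path = global_dir / "interactors.tsv"
        with interactors_path.open("w") as handle:
            handle.write("protein\tclass\n")
            for protein in sorted(results["interactor_classes"]):
                handle.write(
                    f"{protein}\t{results['interactor_classes'][protein]}\n"
                )
        outputs["global/interactors"] = str(interactors_path)

        topology_path = global_dir / "topology.json"
        topology = results["topology"]
        topology_path.write_text(
            json.dumps(
                {
                    "node_count": topology.node_count,
                    "edge_count": topology.edge_count,
                    "average_shortest_path_length":
                        topology.average_shortest_path_length,
                    "average_clustering_coefficient":
                        topology.average_clustering_coefficient,
                    "delta_summary": results["delta_summary"],
                },
                indent=2,
                sort_keys=True,
            )
            + "\n"
        )
        outputs["global/topology"] = str(topology_path)
        return results

    global_results = analyze_global()

    @_stage("enrichment")
    def enrich():
        if gene_sets is None:
            logger.info("no gene sets configured; enrichment skipped")
            return None
        refined = global_results["refined"]
        if not refined:
            logger.warning("no refined central proteins; enrichment skipped")
            return None
        results = enrich_three_settings(
            global_results["global_network"], refined, gene_sets
        )
        enrich_dir = out_dir / "enrichment"
        enrich_dir.mkdir(exist_ok=True)
        for setting, rows in results.items():
            path = enrich_dir / f"{setting}.tsv"
            with path.open("w") as handle:
                handle.write(
                    "set_id\tdescription\toverlap\tquery_size\tset_size\t"
                    "universe_size\tp_value\tadjusted_p\n"
                )
                for r in rows:
                    handle.write(
                        f"{r.set_id}\t{r.description}\t{r.overlap_count}\t"
                        f"{r.query_size}\t{r.set_size}\t{r.universe_size}\t"
                        f"{r.p_value:.12g}\t{r.adjusted_p:.12g}\n"
                    )
            outputs[f"enrichment/{setting}"] = str(path)
        return results

    enrichment = enrich()

    manifest = {
        "package": "crosstalk",
        "version": __version__,
        "config": config.to_manifest_dict(),
        "derived_seeds": {
            "fixture": fixture_seed,
            "propagation": propagation_seed,
            "gene_sets": geneset_seed,
        },
        "phenotypes": [
            {"phenotype_id": s.phenotype_id, "category": s.category,
             "n_seeds": len(s.seeds)}
            for s in seed_sets
        ],
        "outputs": {
            key: {
                "path": str(Path(path).relative_to(out_dir)),
                "sha256": _sha256(Path(path)),
            }
            for key, path in sorted(outputs.items())
        },
    }
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")

    return PipelineResult(
        manifest=manifest,
        interactome=graph,
        seed_sets=list(seed_sets),
        truth=truth,
        score_tables=score_tables,
        networks=networks,
        overlaps=overlaps,
        global_network=global_results["global_network"],
        crosstalk=global_results["crosstalk"],
        central_selection=global_results["selection"],
        central_proteins=global_results["centrals"],
        refined_proteins=global_results["refined"],
        interactor_classes=global_results["interactor_classes"],
        topology=global_results["topology"],
        delta_summary=global_results["delta_summary"],
        enrichment=enrichment,
    )
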