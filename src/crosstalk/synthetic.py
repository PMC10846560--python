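"""Synthetic interactomes with planted disease modules and crosstalk bridges.

Real disease interactomes are proprietary snapshots of integrated databases;
this module generates stand-ins with the statistical structure the analysis
assumes, so every pipeline stage is testable without downloads:

* a scale-free preferential-attachment backbone (PPI networks are scale-free
  and hub-dominated);
* one dense module per phenotype — guilt-by-association presumes disease
  proteins cluster in network neighborhoods — with a controllable membership
  overlap between disease categories and a seed subset per module;
* planted "crosstalk bridge" proteins: non-member, non-seed nodes wired to
  two members of a cardiovascular (CVD) module and two members of the
  cognitive-dysfunction (CD) module, making them eligible linkers of both
  phenotypes and the ground-truth answers for candidate recovery.

Module planting adds edges (never rewires), preserving the scale-free
backbone. All randomness flows from a single explicit seed recorded in the
truth record.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np

from .io import CATEGORIES, GeneSetCollection, SeedSet, write_gmt

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PhenotypeSpec:
    """Specification of one planted phenotype module."""

    phenotype_id: str
    category: str
    module_size: int

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.module_size < 2:
            raise ValueError("module_size must be >= 2")


@dataclass
class SyntheticTruth:
    """Planted ground truth of a synthetic fixture."""

    module_members: dict[str, frozenset[str]]
    module_categories: dict[str, str]
    seeds: dict[str, frozenset[str]]
    bridge_proteins: frozenset[str]
    parameters: dict

    def to_json(self) -> str:
        payload = {
            "module_members": {k: sorted(v) for k, v in self.module_members.items()},
            "module_categories": dict(sorted(self.module_categories.items())),
            "seeds": {k: sorted(v) for k, v in self.seeds.items()},
            "bridge_proteins": sorted(self.bridge_proteins),
            "parameters": self.parameters,
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticTruth":
        payload = json.loads(text)
        return cls(
            module_members={
                k: frozenset(v) for k, v in payload["module_members"].items()
            },
            module_categories=payload["module_categories"],
            seeds={k: frozenset(v) for k, v in payload["seeds"].items()},
            bridge_proteins=frozenset(payload["bridge_proteins"]),
            parameters=payload["parameters"],
        )


def _protein_id(index: int) -> str:
    return f"P{index:05d}"


def generate_interactome(n_nodes: int, attach_m: int, rng_seed: int) -> nx.Graph:
    """Scale-free interactome via preferential attachment.

    Connected simple graph with ``attach_m·(n_nodes − attach_m)`` edges and a
    heavy-tailed degree distribution; deterministic per seed. Nodes carry
    synthetic protein ids ``P00000…``.
    """
    if not n_nodes > attach_m >= 1:
        raise ValueError("need n_nodes > attach_m >= 1")
    backbone = nx.barabasi_albert_graph(n_nodes, attach_m, seed=rng_seed)
    return nx.relabel_nodes(backbone, {i: _protein_id(i) for i in backbone.nodes})


def plant_phenotype_modules(
    interactome: nx.Graph,
    phenotype_specs: Sequence[PhenotypeSpec],
    rng_seed: int,
    module_density: float = 0.3,
    seed_fraction: float = 0.4,
    inter_category_overlap: float = 0.1,
) -> tuple[nx.Graph, list[SeedSet], SyntheticTruth]:
    """Plant one dense module per phenotype and sample its seed proteins.

    Each module draws ``inter_category_overlap`` of its members from modules
    of *other* categories already planted (the oxidative-stress module,
    planted last by convention, thereby straddles both disease categories)
    and the rest from untouched nodes. Random edges are added among members
    until the intra-module density reaches ``module_density``; then
    ``⌈seed_fraction·size⌉`` members are sampled as that phenotype's seeds.
    """
    if not 0.0 < module_density <= 1.0:
        raise ValueError("module_density must lie in (0, 1]")
    if not 0.0 < seed_fraction <= 1.0:
        raise ValueError("seed_fraction must lie in (0, 1]")
    if not 0.0 <= inter_category_overlap < 1.0:
        raise ValueError("inter_category_overlap must lie in [0, 1)")
    if sum(s.module_size for s in phenotype_specs) > interactome.number_of_nodes():
        raise ValueError("module sizes exceed the interactome")
    graph = interactome.copy()
    rng = np.random.default_rng(rng_seed)
    used: set[str] = set()
    members_by_category: dict[str, set[str]] = {c: set() for c in CATEGORIES}
    module_members: dict[str, frozenset[str]] = {}
    module_categories: dict[str, str] = {}
    seeds: dict[str, frozenset[str]] = {}
    seed_sets: list[SeedSet] = []

    for spec in phenotype_specs:
        other_pool = sorted(
            set().union(
                *(members_by_category[c] for c in CATEGORIES if c != spec.category)
            )
        )
        n_overlap = min(
            round(inter_category_overlap * spec.module_size), len(other_pool)
        )
        shared = (
            set(rng.choice(other_pool, size=n_overlap, replace=False))
            if n_overlap
            else set()
        )
        free = sorted(set(graph.nodes) - used - shared)
        n_fresh = spec.module_size - len(shared)
        if n_fresh > len(free):
            raise ValueError(
                f"not enough free nodes for module {spec.phenotype_id!r}"
            )
        fresh = set(rng.choice(free, size=n_fresh, replace=False))
        members = shared | fresh
        used |= members
        members_by_category[spec.category] |= members

        pairs = list(combinations(sorted(members), 2))
        target = math.ceil(module_density * len(pairs))
        existing = [p for p in pairs if graph.has_edge(*p)]
        missing = [p for p in pairs if not graph.has_edge(*p)]
        deficit = target - len(existing)
        if deficit > 0:
            chosen = rng.choice(len(missing), size=deficit, replace=False)
            for idx in sorted(chosen):
                graph.add_edge(*missing[idx])

        n_seeds = math.ceil(seed_fraction * spec.module_size)
        sampled = frozenset(
            rng.choice(sorted(members), size=n_seeds, replace=False)
        )
        module_members[spec.phenotype_id] = frozenset(members)
        module_categories[spec.phenotype_id] = spec.category
        seeds[spec.phenotype_id] = sampled
        seed_sets.append(SeedSet(spec.phenotype_id, spec.category, sampled))

    truth = SyntheticTruth(
        module_members=module_members,
        module_categories=module_categories,
        seeds=seeds,
        bridge_proteins=frozenset(),
        parameters={
            "n_nodes": interactome.number_of_nodes(),
            "module_density": module_density,
            "seed_fraction": seed_fraction,
            "inter_category_overlap": inter_category_overlap,
            "n_bridges": 0,
            "rng_seed": rng_seed,
            "specs": [
                {
                    "phenotype_id": s.phenotype_id,
                    "category": s.category,
                    "module_size": s.module_size,
                }
                for s in phenotype_specs
            ],
        },
    )
    return graph, seed_sets, truth


def plant_crosstalk_bridges(
    interactome: nx.Graph,
    truth: SyntheticTruth,
    n_bridges: int,
    rng_seed: int,
    edges_per_side: int = 2,
) -> tuple[nx.Graph, SyntheticTruth]:
    """Wire bridge proteins between a CVD module and a CD module.

    Each bridge is a non-member, non-seed node given ``edges_per_side``
    edges into one (round-robin chosen) CVD module and the same number into
    one CD module, making it an eligible linker of both phenotypes — the
    planted answer that overlap scoring should recover. Edges preferentially
    target the module's seed members: seeds are always part of the selected
    subnetwork, which is what guarantees the bridge's linker eligibility
    (non-seed members may fall outside the extracted top fraction).
    """
    if n_bridges == 0:
        return interactome, truth
    cvd_modules = sorted(
        ph for ph, c in truth.module_categories.items() if c == "CVD"
    )
    cd_modules = sorted(
        ph for ph, c in truth.module_categories.items() if c == "CD"
    )
    if not cvd_modules or not cd_modules:
        raise ValueError("bridges need at least one CVD and one CD module")
    graph = interactome.copy()
    rng = np.random.default_rng(rng_seed)
    all_members = set().union(*truth.module_members.values())
    free = sorted(set(graph.nodes) - all_members)
    if len(free) < n_bridges:
        raise ValueError("not enough free nodes to plant bridges")
    bridges = sorted(rng.choice(free, size=n_bridges, replace=False))
    for i, bridge in enumerate(bridges):
        cvd_module = cvd_modules[i % len(cvd_modules)]
        cd_module = cd_modules[i % len(cd_modules)]
        for module in (cvd_module, cd_module):
            pool = sorted(truth.seeds[module] - {bridge})
            if len(pool) < edges_per_side:
                pool = sorted(truth.module_members[module] - {bridge})
            targets = rng.choice(pool, size=edges_per_side, replace=False)
            for target in targets:
                graph.add_edge(bridge, target)
    parameters = dict(truth.parameters)
    parameters.update(
        {"n_bridges": n_bridges, "bridge_rng_seed": rng_seed,
         "edges_per_side": edges_per_side}
    )
    new_truth = SyntheticTruth(
        module_members=truth.module_members,
        module_categories=truth.module_categories,
        seeds=truth.seeds,
        bridge_proteins=frozenset(bridges),
        parameters=parameters,
    )
    return graph, new_truth


def default_phenotype_specs(style: str = "headline") -> list[PhenotypeSpec]:
    """Canned module layouts.

    ``headline``: 2 CVD + 1 CD + 1 OS modules of 40 nodes — the fixture for
    the pipeline's parameter-recovery test. ``paper_shaped``: 5 CVD + 2 CD +
    1 OS modules of 40 nodes, matching the 8-phenotype study design and its
    10 + 7 = 17 overlap pairs.
    """
    if style == "headline":
        layout = [("CVD1", "CVD"), ("CVD2", "CVD"), ("CD1", "CD"), ("OS1", "OS")]
    elif style == "paper_shaped":
        layout = [(f"CVD{i}", "CVD") for i in range(1, 6)]
        layout += [("CD1", "CD"), ("CD2", "CD"), ("OS1", "OS")]
    else:
        raise ValueError(f"unknown spec style {style!r}")
    return [PhenotypeSpec(ph, cat, 40) for ph, cat in layout]


def generate_fixture(
    rng_seed: int,
    n_nodes: int = 1000,
    attach_m: int = 3,
    specs: Sequence[PhenotypeSpec] | None = None,
    module_density: float = 0.3,
    seed_fraction: float = 0.4,
    inter_category_overlap: float = 0.1,
    n_bridges: int = 10,
) -> tuple[nx.Graph, list[SeedSet], SyntheticTruth]:
    """Backbone + planted modules + planted bridges in one call."""
    if specs is None:
        specs = default_phenotype_specs("headline")
    rng = np.random.default_rng(rng_seed)
    backbone_seed, module_seed, bridge_seed = (
        int(s) for s in rng.integers(0, 2**31 - 1, size=3)
    )
    backbone = generate_interactome(n_nodes, attach_m, backbone_seed)
    graph, seed_sets, truth = plant_phenotype_modules(
        backbone,
        specs,
        module_seed,
        module_density=module_density,
        seed_fraction=seed_fraction,
        inter_category_overlap=inter_category_overlap,
    )
    graph, truth = plant_crosstalk_bridges(graph, truth, n_bridges, bridge_seed)
    truth.parameters.update({"attach_m": attach_m, "master_rng_seed": rng_seed})
    return graph, seed_sets, truth


def synthetic_gene_sets(
    truth: SyntheticTruth,
    interactome: nx.Graph,
    rng_seed: int,
    n_random_sets: int = 20,
    random_set_size: int = 30,
) -> GeneSetCollection:
    """Gene-set collection for enrichment tests on a synthetic fixture.

    One set per planted module (the planted "pathways", which enrichment
    should flag) plus uniformly drawn decoy sets.
    """
    rng = np.random.default_rng(rng_seed)
    nodes = sorted(interactome.nodes)
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    for phenotype, members in sorted(truth.module_members.items()):
        sets[f"MODULE_{phenotype}"] = (
            f"planted module of {phenotype}", frozenset(members)
        )
    for i in range(n_random_sets):
        members = frozenset(
            rng.choice(nodes, size=random_set_size, replace=False)
        )
        sets[f"DECOY_{i:03d}"] = ("random decoy set", members)
    return GeneSetCollection(sets=sets)


def write_fixture_bundle(
    truth: SyntheticTruth,
    interactome: nx.Graph,
    seed_sets: Sequence[SeedSet],
    out_dir: str | Path,
    gene_sets: GeneSetCollection | None = None,
) -> dict[str, Path]:
    """Write edges.tsv, seeds.tsv, categories.tsv, truth.json (and optional
    pathways.gmt), all byte-deterministic per seed and re-readable by the IO
    module."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "edges": out_dir / "edges.tsv",
        "seeds": out_dir / "seeds.tsv",
        "categories": out_dir / "categories.tsv",
        "truth": out_dir / "truth.json",
    }
    with paths["edges"].open("w") as handle:
        for u, v in sorted(tuple(sorted(e)) for e in interactome.edges):
            handle.write(f"{u}\t{v}\n")
    with paths["seeds"].open("w") as handle:
        for seed_set in seed_sets:
            for gene in sorted(seed_set.seeds):
                handle.write(f"{seed_set.phenotype_id}\t{gene}\n")
    with paths["categories"].open("w") as handle:
        for seed_set in seed_sets:
            handle.write(f"{seed_set.phenotype_id}\t{seed_set.category}\n")
    paths["truth"].write_text(truth.to_json() + "\n")
    if gene_sets is not None:
        paths["gene_sets"] = out_dir / "pathways.gmt"
        write_gmt(gene_sets, paths["gene_sets"])
    return paths
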