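"""Phenotype subnetwork extraction: seeds, top-scoring nodes and linkers.

A phenotype's network is the induced subgraph over its seeds, the
top-scoring fraction of the interactome (2% by default) and the linkers —
nodes outside that selection that interact with at least two selected nodes.
Roles take precedence seed > top > linker when a node qualifies for several.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping

import networkx as nx

from .io import SeedSet, sorted_copy
from .propagation import ScoreTable

logger = logging.getLogger(__name__)

ROLES = ("seed", "top", "linker")


@dataclass(frozen=True)
class PhenotypeNetwork:
    """One phenotype's extracted subnetwork with per-node roles and scores."""

    phenotype_id: str
    category: str
    subgraph: nx.Graph
    roles: Mapping[str, str]
    scores: Mapping[str, float]

    @property
    def nodes(self) -> set[str]:
        return set(self.subgraph.nodes)

    def nodes_with_role(self, role: str) -> set[str]:
        return {v for v, r in self.roles.items() if r == role}


def select_top_fraction(
    score_table: ScoreTable,
    fraction: float,
    seed_set: SeedSet | None = None,
) -> set[str]:
    """The ``⌈fraction·|nodes|⌉`` highest-scoring proteins.

    Seeds compete in the same pool as every other node (they usually score 1
    and therefore occupy top slots). Ties at the cutoff are broken by
    lexicographic protein id so the selection is deterministic.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    n = len(score_table.scores)
    k = math.ceil(fraction * n)
    if k < 1:
        raise ValueError("fraction selects no nodes")
    return set(score_table.top(k))


def find_linkers(graph: nx.Graph, selected: set[str]) -> set[str]:
    """Nodes outside ``selected`` adjacent to at least two selected nodes."""
    missing = selected - set(graph.nodes)
    if missing:
        raise ValueError(f"selected nodes not in graph: {sorted(missing)[:5]}")
    linkers = set()
    for node in graph.nodes:
        if node in selected:
            continue
        count = 0
        for neighbor in graph.neighbors(node):
            if neighbor in selected:
                count += 1
                if count >= 2:
                    linkers.add(node)
                    break
    return linkers


def induced_subgraph(graph: nx.Graph, nodes: set[str]) -> nx.Graph:
    """Induced subgraph with sorted node/edge insertion (reproducible IO)."""
    return sorted_copy(graph.subgraph(nodes))


def build_phenotype_network(
    interactome: nx.Graph,
    score_table: ScoreTable,
    seed_set: SeedSet,
    fraction: float = 0.02,
    max_linkers: int | None = None,
) -> PhenotypeNetwork:
    """Extract the phenotype network: seeds ∪ top fraction ∪ their linkers.

    Seeds falling outside the top fraction are still included, with role
    ``seed``. ``max_linkers`` optionally keeps only the highest-scoring
    linkers (score desc, id asc); default keeps all.
    """
    top = select_top_fraction(score_table, fraction, seed_set)
    selected = set(seed_set.seeds) | top
    linkers = find_linkers(interactome, selected)
    if max_linkers is not None and len(linkers) > max_linkers:
        ranked = sorted(linkers, key=lambda v: (-score_table.scores[v], v))
        linkers = set(ranked[:max_linkers])
    members = selected | linkers
    roles = {}
    for node in members:
        if node in seed_set.seeds:
            roles[node] = "seed"
        elif node in top:
            roles[node] = "top"
        else:
            roles[node] = "linker"
    subgraph = induced_subgraph(interactome, members)
    scores = {v: float(score_table.scores[v]) for v in members}
    return PhenotypeNetwork(
        phenotype_id=seed_set.phenotype_id,
        category=seed_set.category,
        subgraph=subgraph,
        roles=roles,
        scores=scores,
    )


def write_phenotype_network(network: PhenotypeNetwork, path) -> None:
    """Write a phenotype network as GraphML with role/score/phenotype attrs."""
    annotated = sorted_copy(network.subgraph)
    for node in annotated.nodes:
        annotated.nodes[node]["role"] = network.roles[node]
        annotated.nodes[node]["score"] = float(network.scores[node])
        annotated.nodes[node]["phenotype_id"] = network.phenotype_id
        annotated.nodes[node]["category"] = network.category
    nx.write_graphml(annotated, path)


def read_phenotype_network(path) -> PhenotypeNetwork:
    """Read a GraphML file written by :func:`write_phenotype_network`."""
    graph = nx.read_graphml(path)
    if graph.number_of_nodes() == 0:
        raise ValueError(f"{path}: empty phenotype network")
    first = next(iter(graph.nodes))
    phenotype_id = graph.nodes[first]["phenotype_id"]
    category = graph.nodes[first]["category"]
    roles = {v: graph.nodes[v]["role"] for v in graph.nodes}
    scores = {v: float(graph.nodes[v]["score"]) for v in graph.nodes}
    plain = nx.Graph()
    plain.add_nodes_from(graph.nodes)
    plain.add_edges_from(graph.edges)
    return PhenotypeNetwork(
        phenotype_id=phenotype_id,
        category=category,
        subgraph=sorted_copy(plain),
        roles=roles,
        scores=scores,
    )
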