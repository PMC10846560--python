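"""Pairwise overlap networks between phenotype networks and crosstalk
candidate ranking.

The overlap of two phenotype networks is built on the intersection of their
node sets; a shared node's overlap score is the mean of its two parent
propagation scores, the statistic used to rank candidate crosstalk proteins.
Candidates exclude anything curated as a seed in either parent, since the
point of the ranking is novelty.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import product
from typing import Mapping, Sequence

import networkx as nx

from .io import sorted_copy
from .subnetwork import PhenotypeNetwork

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class OverlapNetwork:
    """Overlap of two phenotype networks over their shared proteins."""

    pair: tuple[str, str]
    subgraph: nx.Graph
    overlap_scores: Mapping[str, float]
    roles_1: Mapping[str, str]
    roles_2: Mapping[str, str]
    categories: tuple[str, str]

    @property
    def nodes(self) -> set[str]:
        return set(self.subgraph.nodes)


def overlap_score(score_1: float, score_2: float) -> float:
    """Mean of a protein's scores in the two parent phenotypes."""
    for s in (score_1, score_2):
        if not 0.0 <= s <= 1.0:
            raise ValueError(f"score {s} outside [0, 1]")
    return (score_1 + score_2) / 2.0


def overlap_network(
    net_1: PhenotypeNetwork,
    net_2: PhenotypeNetwork,
    edge_mode: str = "union",
) -> OverlapNetwork:
    """Build the overlap network of two phenotype networks.

    Nodes are the intersection of the parents' node sets. With
    ``edge_mode="union"`` (default) an edge is kept if either parent contains
    it between two shared nodes — the connected view; ``"intersection"``
    keeps only edges present in both. The operation is symmetric up to pair
    ordering.
    """
    if edge_mode not in {"union", "intersection"}:
        raise ValueError(f"unknown edge_mode {edge_mode!r}")
    shared = net_1.nodes & net_2.nodes
    if not shared:
        logger.warning(
            "phenotypes %s and %s share no proteins; empty overlap",
            net_1.phenotype_id, net_2.phenotype_id,
        )
    graph = nx.Graph()
    graph.add_nodes_from(sorted(shared))
    edges_1 = {tuple(sorted(e)) for e in net_1.subgraph.edges}
    edges_2 = {tuple(sorted(e)) for e in net_2.subgraph.edges}
    pool = edges_1 | edges_2 if edge_mode == "union" else edges_1 & edges_2
    for u, v in sorted(pool):
        if u in shared and v in shared:
            graph.add_edge(u, v)
    scores = {
        v: overlap_score(net_1.scores[v], net_2.scores[v]) for v in sorted(shared)
    }
    return OverlapNetwork(
        pair=(net_1.phenotype_id, net_2.phenotype_id),
        subgraph=sorted_copy(graph),
        overlap_scores=scores,
        roles_1={v: net_1.roles[v] for v in shared},
        roles_2={v: net_2.roles[v] for v in shared},
        categories=(net_1.category, net_2.category),
    )


def top_candidates(
    overlap: OverlapNetwork, k: int
) -> list[tuple[str, float, str, str]]:
    """Rank candidate crosstalk proteins of one overlap network.

    Proteins that are seeds in either parent are excluded; the rest are
    sorted by overlap score descending with lexicographic tiebreak, and the
    first ``k`` are returned as ``(protein, overlap_score, role_1, role_2)``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    candidates = [
        v for v in overlap.nodes
        if overlap.roles_1[v] != "seed" and overlap.roles_2[v] != "seed"
    ]
    candidates.sort(key=lambda v: (-overlap.overlap_scores[v], v))
    if len(candidates) < k:
        logger.warning(
            "overlap %s has only %d candidate(s) (< k=%d)",
            overlap.pair, len(candidates), k,
        )
    return [
        (v, overlap.overlap_scores[v], overlap.roles_1[v], overlap.roles_2[v])
        for v in candidates[:k]
    ]


def ranked_candidates(overlap: OverlapNetwork) -> list[tuple[str, float, str, str]]:
    """All non-seed candidates of an overlap network, fully ranked."""
    n = len(overlap.nodes)
    return top_candidates(overlap, k=n) if n else []


def pairwise_score_ranking(
    scores_1: Mapping[str, float],
    scores_2: Mapping[str, float],
    exclude: frozenset[str] | set[str] = frozenset(),
) -> list[tuple[str, float]]:
    """Rank every protein by the mean of its two phenotype scores.

    The network-wide extension of the overlap score: propagation scores
    cover every interactome node, so the averaged score ranks all proteins,
    not only those inside the extracted overlap subnetwork. ``exclude``
    removes curated proteins (typically the union of both phenotypes'
    seeds) from the candidate list. Sorted score-descending with
    lexicographic tiebreak.
    """
    if set(scores_1) != set(scores_2):
        raise ValueError("score tables cover different node sets")
    ranked = [
        (v, (scores_1[v] + scores_2[v]) / 2.0)
        for v in scores_1 if v not in exclude
    ]
    ranked.sort(key=lambda item: (-item[1], item[0]))
    return ranked


def all_pairwise_overlaps(
    networks: Sequence[PhenotypeNetwork],
    pairing: str = "all",
    edge_mode: str = "union",
) -> list[OverlapNetwork]:
    """Overlap networks for the requested category pairing.

    ``cvd_vs_cd`` pairs every CVD phenotype with every CD phenotype;
    ``vs_os`` pairs every non-OS phenotype with every OS phenotype; ``all``
    concatenates both lists (|CVD|·|CD| + (|CVD|+|CD|)·|OS| pairs).
    """
    if pairing not in {"cvd_vs_cd", "vs_os", "all"}:
        raise ValueError(f"unknown pairing {pairing!r}")
    if len(networks) < 2:
        return []
    cvd = [n for n in networks if n.category == "CVD"]
    cd = [n for n in networks if n.category == "CD"]
    os_nets = [n for n in networks if n.category == "OS"]
    pairs: list[tuple[PhenotypeNetwork, PhenotypeNetwork]] = []
    if pairing in {"cvd_vs_cd", "all"}:
        pairs.extend(product(cvd, cd))
    if pairing in {"vs_os", "all"}:
        pairs.extend(product(cvd + cd, os_nets))
    return [overlap_network(a, b, edge_mode=edge_mode) for a, b in pairs]
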