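"""The Global Network: merged phenotype networks, centrality analysis and the
dual stress-included/excluded crosstalk scoring.

Merging takes the set-theoretic union of all phenotype subnetworks and labels
each protein by the disease categories of the phenotypes it came from (CVD,
CD, OS and their "&"-joined combinations). Candidate hubs are the top-k
proteins per category group by normalized degree or betweenness centrality.
The dual score compares, per protein, the mean of its per-category maximum
propagation scores with and without the oxidative-stress score; the shift
``delta = os_included − os_excluded`` flags stress-sensitive proteins and is
algebraically bounded by 1/3.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .io import CATEGORIES, sorted_copy
from .propagation import ScoreTable
from .subnetwork import PhenotypeNetwork

logger = logging.getLogger(__name__)

INTERACTOR_CLASSES = ("cvd_only", "cd_only", "both", "os_only")


@dataclass
class GlobalNetwork:
    """Union of phenotype networks with provenance and centrality annotations."""

    subgraph: nx.Graph
    origin: Mapping[str, frozenset[str]]
    category_label: Mapping[str, str]
    phenotype_categories: Mapping[str, str]
    degree_centrality: Mapping[str, float] | None = None
    betweenness_centrality: Mapping[str, float] | None = None

    @property
    def nodes(self) -> set[str]:
        return set(self.subgraph.nodes)


@dataclass(frozen=True)
class TopologySummary:
    """Coarse topology of the Global Network."""

    node_count: int
    edge_count: int
    average_shortest_path_length: float
    average_clustering_coefficient: float


def _label_for(categories: set[str]) -> str:
    return "&".join(c for c in CATEGORIES if c in categories)


def merge_networks(
    networks: Sequence[PhenotypeNetwork],
    category_map: Mapping[str, str],
) -> GlobalNetwork:
    """Merge phenotype networks into the Global Network.

    Node and edge sets are unions over the member networks; each node records
    the set of phenotypes it originates from, projected onto categories and
    joined with "&" in canonical CVD, CD, OS order.
    """
    if len(networks) < 2:
        raise ValueError("need at least two phenotype networks to merge")
    for net in networks:
        if net.phenotype_id not in category_map:
            raise KeyError(
                f"phenotype {net.phenotype_id!r} missing from category map"
            )
    union = nx.Graph()
    origin: dict[str, set[str]] = {}
    for net in networks:
        for node in net.subgraph.nodes:
            union.add_node(node)
            origin.setdefault(node, set()).add(net.phenotype_id)
        union.add_edges_from(net.subgraph.edges)
    labels = {
        node: _label_for({category_map[ph] for ph in origins})
        for node, origins in origin.items()
    }
    return GlobalNetwork(
        subgraph=sorted_copy(union),
        origin={n: frozenset(o) for n, o in origin.items()},
        category_label=labels,
        phenotype_categories=dict(category_map),
    )


def compute_centralities(global_net: GlobalNetwork) -> GlobalNetwork:
    """Annotate every node with normalized degree and betweenness centrality.

    Degree centrality is deg(v)/(n−1); betweenness is shortest-path
    betweenness normalized by 2/((n−1)(n−2)) so values are comparable across
    network sizes.
    """
    if global_net.subgraph.number_of_nodes() < 3:
        raise ValueError("centrality analysis needs at least 3 nodes")
    global_net.degree_centrality = nx.degree_centrality(global_net.subgraph)
    global_net.betweenness_centrality = nx.betweenness_centrality(
        global_net.subgraph, normalized=True
    )
    return global_net


def crosstalk_scores(
    score_tables: Sequence[ScoreTable],
    category_map: Mapping[str, str],
    universe: Iterable[str],
) -> pd.DataFrame:
    """Per-protein dual crosstalk scores over ``universe``.

    For each protein: ``cvd_max``/``cd_max`` are the maxima over the CVD/CD
    phenotype score tables, ``os_score`` comes from the single OS table,
    ``os_excluded = (cvd_max + cd_max)/2``,
    ``os_included = (cvd_max + cd_max + os_score)/3`` and
    ``delta = os_included − os_excluded``. Since all scores lie in [0, 1],
    ``delta = (os_score − os_excluded)/3`` and ``|delta| ≤ 1/3``.
    """
    by_category: dict[str, list[ScoreTable]] = {c: [] for c in CATEGORIES}
    for table in score_tables:
        if table.phenotype_id not in category_map:
            raise KeyError(f"phenotype {table.phenotype_id!r} not in category map")
        by_category[category_map[table.phenotype_id]].append(table)
    if not by_category["CVD"] or not by_category["CD"]:
        raise ValueError("need at least one CVD and one CD score table")
    if len(by_category["OS"]) != 1:
        raise ValueError(
            f"need exactly one OS score table, got {len(by_category['OS'])}"
        )
    proteins = sorted(universe)
    for table in score_tables:
        missing = [p for p in proteins if p not in table.scores]
        if missing:
            raise ValueError(
                f"table {table.phenotype_id!r} lacks scores for "
                f"{missing[:5]}..."
            )

    def column(tables: list[ScoreTable]) -> np.ndarray:
        data = np.array([[t.scores[p] for p in proteins] for t in tables])
        return data.max(axis=0)

    cvd_max = column(by_category["CVD"])
    cd_max = column(by_category["CD"])
    os_score = column(by_category["OS"])
    os_excluded = (cvd_max + cd_max) / 2.0
    os_included = (cvd_max + cd_max + os_score) / 3.0
    frame = pd.DataFrame(
        {
            "cvd_max": cvd_max,
            "cd_max": cd_max,
            "os_score": os_score,
            "os_excluded": os_excluded,
            "os_included": os_included,
            "delta": os_included - os_excluded,
        },
        index=pd.Index(proteins, name="protein"),
    )
    return frame


def select_central(
    global_net: GlobalNetwork,
    k: int = 5,
    restrict: str = "os_related",
) -> dict[str, dict[str, list[str]]]:
    """Top-k proteins per category group by degree and by betweenness.

    Groups are the "&"-joined category labels; ``restrict="os_related"``
    keeps only groups containing OS (the stress-related proteins),
    ``"non_os"`` the complement, ``"all"`` everything. A protein may appear
    in both measures' lists; ties break lexicographically.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if restrict not in {"os_related", "non_os", "all"}:
        raise ValueError(f"unknown restrict mode {restrict!r}")
    if global_net.degree_centrality is None:
        raise ValueError("run compute_centralities first")
    groups: dict[str, list[str]] = {}
    for node, label in global_net.category_label.items():
        groups.setdefault(label, []).append(node)
    selection: dict[str, dict[str, list[str]]] = {}
    for label in sorted(groups):
        os_related = "OS" in label.split("&")
        if restrict == "os_related" and not os_related:
            continue
        if restrict == "non_os" and os_related:
            continue
        members = groups[label]
        by_degree = sorted(
            members, key=lambda v: (-global_net.degree_centrality[v], v)
        )[:k]
        by_betweenness = sorted(
            members, key=lambda v: (-global_net.betweenness_centrality[v], v)
        )[:k]
        selection[label] = {"degree": by_degree, "betweenness": by_betweenness}
    return selection


def central_union(selection: Mapping[str, Mapping[str, list[str]]]) -> set[str]:
    """Unique proteins appearing in any group's degree or betweenness list."""
    out: set[str] = set()
    for lists in selection.values():
        for proteins in lists.values():
            out.update(proteins)
    return out


def filter_by_delta(
    scores: pd.DataFrame, proteins: Iterable[str], threshold: float = 0.1
) -> set[str]:
    """Proteins whose dual-score shift satisfies ``|delta| ≥ threshold``.

    The comparison is inclusive: a protein shifted by exactly the threshold
    counts as stress-affected.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    return {p for p in proteins if abs(scores.at[p, "delta"]) >= threshold}


def classify_interactors(
    global_net: GlobalNetwork, centrals: Iterable[str]
) -> dict[str, str]:
    """Classify the pooled neighbors of the central proteins by category.

    Neighbors (centrals themselves excluded) are assigned ``cvd_only`` if
    their origin includes a CVD phenotype but no CD phenotype, ``cd_only``
    symmetrically, ``both`` if both, and ``os_only`` if neither (possible
    when a neighbor only occurs in the OS network). The assignment is a
    partition of the pooled neighborhood.
    """
    centrals = set(centrals)
    missing = centrals - global_net.nodes
    if missing:
        raise ValueError(f"central proteins not in network: {sorted(missing)[:5]}")
    pooled: set[str] = set()
    for central in centrals:
        pooled.update(global_net.subgraph.neighbors(central))
    pooled -= centrals
    classes: dict[str, str] = {}
    for node in sorted(pooled):
        cats = {
            global_net.phenotype_categories[ph] for ph in global_net.origin[node]
        }
        has_cvd, has_cd = "CVD" in cats, "CD" in cats
        if has_cvd and has_cd:
            classes[node] = "both"
        elif has_cvd:
            classes[node] = "cvd_only"
        elif has_cd:
            classes[node] = "cd_only"
        else:
            classes[node] = "os_only"
    return classes


def summarize_topology(global_net: GlobalNetwork) -> TopologySummary:
    """Average shortest path (largest connected component) and mean local
    clustering coefficient (degree < 2 nodes contribute 0)."""
    graph = global_net.subgraph
    if graph.number_of_nodes() < 2:
        raise ValueError("topology summary needs at least 2 nodes")
    if graph.number_of_edges() == 0:
        logger.warning("edgeless network: average path length reported as 0")
        path_length = 0.0
    else:
        component = max(nx.connected_components(graph), key=len)
        path_length = nx.average_shortest_path_length(graph.subgraph(component))
    clustering = nx.average_clustering(graph)
    return TopologySummary(
        node_count=graph.number_of_nodes(),
        edge_count=graph.number_of_edges(),
        average_shortest_path_length=float(path_length),
        average_clustering_coefficient=float(clustering),
    )


def delta_distribution(
    scores: pd.DataFrame, threshold: float = 0.1, bins: int = 20
) -> dict:
    """Distribution of the dual-score shift over the scored universe.

    Returns counts of proteins with ``delta ≥ +threshold``, ``≤ −threshold``
    and strictly between, a histogram over [−1/3, 1/3], and the maximum
    absolute shift (always < 1/3 by the score algebra).
    """
    delta = scores["delta"].to_numpy()
    above = int((delta >= threshold).sum())
    below = int((delta <= -threshold).sum())
    counts, edges = np.histogram(delta, bins=bins, range=(-1 / 3, 1 / 3))
    return {
        "above": above,
        "below": below,
        "middle": int(len(delta) - above - below),
        "total": int(len(delta)),
        "max_abs_delta": float(np.abs(delta).max()) if len(delta) else 0.0,
        "histogram_counts": counts.tolist(),
        "histogram_edges": edges.tolist(),
    }


def write_global_network(global_net: GlobalNetwork, path) -> None:
    """Write the Global Network as GraphML with provenance and centralities."""
    annotated = sorted_copy(global_net.subgraph)
    for node in annotated.nodes:
        annotated.nodes[node]["origin"] = ",".join(sorted(global_net.origin[node]))
        annotated.nodes[node]["category_label"] = global_net.category_label[node]
        if global_net.degree_centrality is not None:
            annotated.nodes[node]["degree_centrality"] = float(
                global_net.degree_centrality[node]
            )
            annotated.nodes[node]["betweenness_centrality"] = float(
                global_net.betweenness_centrality[node]
            )
    nx.write_graphml(annotated, path)
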