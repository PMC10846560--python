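"""Guilt-by-association scoring of interactome nodes by seed propagation.

Four ranking algorithms in the GUILD family are provided, reimplemented from
their published descriptions as explicit, testable update rules (this module
is not the original C++ program and does not claim bit-identical numerics):

* **netshort** — scores a node by its proximity to seeds along paths whose
  edges are cheapened when their endpoints carry seed information:
  ``w(u,v) = 1/(1 + s0(u) + s0(v))`` and ``raw(v) = Σ_seeds t≠v 1/d_w(v,t)``.
* **netzcore** — synchronous neighbor averaging of the seed indicator,
  z-scored against the same averaging on an ensemble of degree-preserving
  rewired null networks.
* **netscore** — damped message passing ``s ← (1−λ)·s_base + λ·A D⁻¹ s``
  run for ``iterations`` rounds within each of ``repetitions`` repetitions;
  the base score is re-anchored (min–max rescaled) between repetitions.
* **netcombo** — the consensus: each of the three tables standardized to
  zero mean/unit variance, averaged elementwise, rescaled.

Every final score table is min–max scaled to [0, 1]; when all raw scores are
equal the table degenerates to a uniform 0.5.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import scipy.sparse as sp

from .io import SeedSet

logger = logging.getLogger(__name__)

ALGORITHMS = ("netshort", "netzcore", "netscore", "netcombo")


@dataclass(frozen=True)
class PropagationParams:
    """Knobs of the propagation algorithms.

    Parameters
    ----------
    rng_seed:
        Master seed for the degree-preserving null ensemble. Required — there
        is no silent default, so every run is reproducible by construction.
    repetitions, iterations:
        netscore's outer repetitions and inner message-passing rounds.
    damping:
        netscore's mixing weight λ ∈ [0, 1] between the anchored base score
        and the incoming neighbor messages.
    null_replicates:
        Number of rewired replicates in netzcore's null ensemble.
    rewire_swaps_per_edge:
        Double-edge swaps attempted per edge when rewiring a null replicate.
    """

    rng_seed: int
    repetitions: int = 3
    iterations: int = 2
    damping: float = 0.5
    null_replicates: int = 100
    rewire_swaps_per_edge: int = 10

    def __post_init__(self) -> None:
        if self.repetitions < 1 or self.iterations < 1:
            raise ValueError("repetitions and iterations must be >= 1")
        if not 0.0 <= self.damping <= 1.0:
            raise ValueError("damping must lie in [0, 1]")
        if self.null_replicates < 1:
            raise ValueError("null_replicates must be >= 1")
        if self.rewire_swaps_per_edge < 1:
            raise ValueError("rewire_swaps_per_edge must be >= 1")


@dataclass(frozen=True)
class ScoreTable:
    """Per-phenotype node scores in [0, 1] covering every interactome node."""

    phenotype_id: str
    algorithm: str
    scores: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}")

    def top(self, k: int) -> list[str]:
        """The ``k`` highest-scoring proteins (score desc, id asc)."""
        return sorted(self.scores, key=lambda p: (-self.scores[p], p))[:k]


def initial_scores(graph: nx.Graph, seed_set: SeedSet) -> dict[str, float]:
    """Seed indicator: 1 for seed proteins, 0 for every other node."""
    missing = seed_set.seeds - set(graph.nodes)
    if missing:
        raise ValueError(
            f"seeds not in interactome: {sorted(missing)[:5]}"
        )
    return {v: (1.0 if v in seed_set.seeds else 0.0) for v in graph.nodes}


def minmax_scale(raw: Mapping[str, float]) -> dict[str, float]:
    """Scale values to [0, 1]; a constant table maps to a uniform 0.5."""
    if not raw:
        raise ValueError("cannot scale an empty score mapping")
    values = np.asarray(list(raw.values()), dtype=float)
    if np.isnan(values).any():
        raise ValueError("NaN in raw scores")
    lo, hi = values.min(), values.max()
    if hi == lo:
        return {k: 0.5 for k in raw}
    return {k: (v - lo) / (hi - lo) for k, v in raw.items()}


def _minmax_vec(values: np.ndarray) -> np.ndarray:
    lo, hi = values.min(), values.max()
    if hi == lo:
        return np.full_like(values, 0.5)
    return (values - lo) / (hi - lo)


def _node_order(graph: nx.Graph) -> list[str]:
    return sorted(graph.nodes)


def _seed_vector(nodes: Sequence[str], seed_set: SeedSet) -> np.ndarray:
    return np.asarray([1.0 if v in seed_set.seeds else 0.0 for v in nodes])


def netshort(graph: nx.Graph, seed_set: SeedSet) -> ScoreTable:
    """Score nodes by closeness to seeds over seed-cheapened shortest paths.

    Each edge costs ``1/(1 + s0(u) + s0(v))`` so paths through seeds are
    short; a node accumulates ``1/d`` over its weighted distance ``d`` to
    every seed other than itself (unreachable seeds contribute 0). Seeds are
    then pinned to the maximum raw score so that a phenotype never ranks its
    own seeds below predicted associations, and the table is min–max scaled.
    """
    s0 = initial_scores(graph, seed_set)
    weighted = nx.Graph()
    weighted.add_nodes_from(graph.nodes)
    for u, v in graph.edges:
        weighted.add_edge(u, v, weight=1.0 / (1.0 + s0[u] + s0[v]))
    raw = {v: 0.0 for v in graph.nodes}
    for seed in sorted(seed_set.seeds):
        distances = nx.single_source_dijkstra_path_length(
            weighted, seed, weight="weight"
        )
        for node, dist in distances.items():
            if node != seed:
                raw[node] += 1.0 / dist
    peak = max(raw.values())
    for seed in seed_set.seeds:
        raw[seed] = peak
    return ScoreTable(seed_set.phenotype_id, "netshort", minmax_scale(raw))


def rewire_preserving_degree(
    graph: nx.Graph, swaps_per_edge: int, rng_seed: int
) -> nx.Graph:
    """Randomize edges by double-edge swaps, preserving every node's degree.

    Returns a new simple graph with the same degree sequence; deterministic
    for a given ``rng_seed``. Graphs admitting no legal swap (too few edges
    or nodes) are returned unchanged with a warning.
    """
    rewired = graph.copy()
    n_edges = rewired.number_of_edges()
    if n_edges < 2 or rewired.number_of_nodes() < 4:
        logger.warning("graph admits no double-edge swap; returned unchanged")
        return rewired
    nswap = swaps_per_edge * n_edges
    try:
        nx.double_edge_swap(
            rewired, nswap=nswap, max_tries=100 * nswap, seed=rng_seed
        )
    except nx.NetworkXError as exc:
        logger.warning("rewiring aborted (%s); returned partial rewiring", exc)
    return rewired


def null_ensemble(graph: nx.Graph, params: PropagationParams) -> list[nx.Graph]:
    """Degree-preserving rewired replicates for netzcore's null model.

    Generated once per interactome and reusable across phenotypes (the null
    depends only on topology, not on the seed set).
    """
    rng = np.random.default_rng(params.rng_seed)
    child_seeds = rng.integers(0, 2**31 - 1, size=params.null_replicates)
    return [
        rewire_preserving_degree(graph, params.rewire_swaps_per_edge, int(s))
        for s in child_seeds
    ]


def _averaging_operator(
    graph: nx.Graph, nodes: Sequence[str]
) -> tuple[sp.csr_matrix, np.ndarray]:
    """Row-stochastic neighbor-averaging operator and isolated-node mask."""
    adjacency = nx.to_scipy_sparse_array(graph, nodelist=list(nodes), format="csr")
    degrees = np.asarray(adjacency.sum(axis=1)).ravel()
    isolated = degrees == 0
    inv_deg = np.where(isolated, 0.0, 1.0 / np.where(isolated, 1.0, degrees))
    operator = sp.diags(inv_deg) @ adjacency
    return sp.csr_matrix(operator), isolated


def _neighbor_average(
    operator: sp.csr_matrix, isolated: np.ndarray, s0: np.ndarray, iterations: int
) -> np.ndarray:
    """``iterations`` synchronous rounds of mean-over-neighbors updates.

    Isolated nodes have no neighbors to average and keep their initial score.
    """
    s = s0.copy()
    for _ in range(iterations):
        s = operator @ s
        s[isolated] = s0[isolated]
    return s


def netzcore(
    graph: nx.Graph,
    seed_set: SeedSet,
    params: PropagationParams,
    null_graphs: Sequence[nx.Graph] | None = None,
) -> ScoreTable:
    """Neighbor-averaged seed scores z-scored against rewired null networks.

    The observed score of a node after ``iterations`` rounds of synchronous
    neighbor averaging is compared with the distribution of the same quantity
    over ``null_replicates`` degree-preserving rewirings:
    ``z(v) = (raw(v) − μ_null(v)) / σ_null(v)``, with ``z = 0`` wherever the
    null is rigid (σ = 0). z-scores are min–max scaled.
    """
    if params.null_replicates < 2 and null_graphs is None:
        raise ValueError("netzcore needs at least 2 null replicates")
    nodes = _node_order(graph)
    s0 = _seed_vector(nodes, seed_set)
    operator, isolated = _averaging_operator(graph, nodes)
    raw = _neighbor_average(operator, isolated, s0, params.iterations)

    if null_graphs is None:
        null_graphs = null_ensemble(graph, params)
    null_scores = np.empty((len(null_graphs), len(nodes)))
    for i, null_graph in enumerate(null_graphs):
        null_op, null_iso = _averaging_operator(null_graph, nodes)
        null_scores[i] = _neighbor_average(null_op, null_iso, s0, params.iterations)
    mu = null_scores.mean(axis=0)
    sigma = null_scores.std(axis=0)
    z = np.where(sigma > 0, (raw - mu) / np.where(sigma > 0, sigma, 1.0), 0.0)
    scaled = _minmax_vec(z)
    return ScoreTable(seed_set.phenotype_id, "netzcore", dict(zip(nodes, scaled)))


def netscore(
    graph: nx.Graph, seed_set: SeedSet, params: PropagationParams
) -> ScoreTable:
    """Damped message passing from seeds with periodic re-anchoring.

    Within each repetition, ``iterations`` rounds of
    ``s ← (1−λ)·s_base + λ·Σ_{u∈N(v)} s(u)/deg(u)`` spread each node's score
    equally over its neighbors; after a repetition the accumulated scores are
    min–max rescaled and become the new base, letting information travel
    further than ``iterations`` hops without exploding.
    """
    nodes = _node_order(graph)
    lam = params.damping
    adjacency = nx.to_scipy_sparse_array(graph, nodelist=nodes, format="csr")
    degrees = np.asarray(adjacency.sum(axis=1)).ravel()
    safe_deg = np.where(degrees > 0, degrees, 1.0)
    base = _seed_vector(nodes, seed_set)
    for _ in range(params.repetitions):
        s = base.copy()
        for _ in range(params.iterations):
            s = (1.0 - lam) * base + lam * (adjacency @ (s / safe_deg))
        base = _minmax_vec(s)
    return ScoreTable(seed_set.phenotype_id, "netscore", dict(zip(nodes, base)))


def netcombo(t1: ScoreTable, t2: ScoreTable, t3: ScoreTable) -> ScoreTable:
    """Consensus of three score tables: standardize, average, rescale.

    Each table is brought to zero mean and unit variance (a constant table
    contributes a zero vector), the three are averaged elementwise, and the
    result is min–max scaled.
    """
    domain = set(t1.scores)
    if set(t2.scores) != domain or set(t3.scores) != domain:
        raise ValueError("score tables cover different node sets")
    if not (t1.phenotype_id == t2.phenotype_id == t3.phenotype_id):
        raise ValueError("score tables belong to different phenotypes")
    nodes = sorted(domain)
    stacked = np.array([[t.scores[v] for v in nodes] for t in (t1, t2, t3)])
    means = stacked.mean(axis=1, keepdims=True)
    stds = stacked.std(axis=1, keepdims=True)
    standardized = np.where(stds > 0, (stacked - means) / np.where(stds > 0, stds, 1.0), 0.0)
    combined = _minmax_vec(standardized.mean(axis=0))
    return ScoreTable(t1.phenotype_id, "netcombo", dict(zip(nodes, combined)))


def score_phenotype(
    graph: nx.Graph,
    seed_set: SeedSet,
    params: PropagationParams,
    null_graphs: Sequence[nx.Graph] | None = None,
    return_components: bool = False,
) -> ScoreTable | tuple[ScoreTable, dict[str, ScoreTable]]:
    """Full prioritization of one phenotype: the netcombo consensus score.

    Runs netshort, netzcore and netscore and combines them. Pass
    ``null_graphs`` (from :func:`null_ensemble`) to share one rewired
    ensemble across phenotypes; with ``return_components`` the three
    component tables are returned alongside the consensus.
    """
    short = netshort(graph, seed_set)
    zcore = netzcore(graph, seed_set, params, null_graphs=null_graphs)
    score = netscore(graph, seed_set, params)
    combo = netcombo(score, zcore, short)
    if return_components:
        return combo, {"netshort": short, "netzcore": zcore, "netscore": score}
    return combo
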