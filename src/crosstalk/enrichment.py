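"""Over-representation analysis of protein sets against gene-set collections.

One-sided hypergeometric upper-tail tests with Benjamini–Hochberg FDR
control. The headline use is the three-setting analysis of the refined
central proteins: enriched together with their CVD interactors, their CD
interactors, and the interactors common to both categories.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .global_network import GlobalNetwork, classify_interactors
from .io import GeneSetCollection

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnrichmentResult:
    set_id: str
    description: str
    overlap_count: int
    query_size: int
    set_size: int
    universe_size: int
    p_value: float
    adjusted_p: float


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjusted p-values, original order kept."""
    for p in p_values:
        if not 0.0 < p <= 1.0:
            raise ValueError(f"p-value {p} outside (0, 1]")
    if not p_values:
        return []
    _, adjusted, _, _ = multipletests(list(p_values), method="fdr_bh")
    return [float(q) for q in adjusted]


def hypergeom_enrich(
    query: Iterable[str],
    universe: Iterable[str],
    collection: GeneSetCollection,
    min_set_size: int = 3,
) -> list[EnrichmentResult]:
    """Hypergeometric over-representation of ``query`` in each gene set.

    Gene sets are first intersected with the universe; sets retaining fewer
    than ``min_set_size`` members are skipped (logged). The p-value is the
    upper tail P(X ≥ overlap) of drawing |query| proteins from the universe.
    Results are BH-adjusted jointly and sorted by p ascending (set id
    tiebreak).
    """
    query = set(query)
    universe = set(universe)
    if not query:
        raise ValueError("empty query")
    if not universe:
        raise ValueError("empty universe")
    if not query <= universe:
        raise ValueError("query must be a subset of the universe")
    rows: list[tuple[str, str, int, int]] = []
    skipped = 0
    for set_id in sorted(collection.sets):
        description, members = collection.sets[set_id]
        members = members & universe
        if len(members) < min_set_size:
            skipped += 1
            continue
        rows.append((set_id, description, len(members), len(query & members)))
    if skipped:
        logger.info("skipped %d gene set(s) with < %d members in the universe",
                    skipped, min_set_size)
    m_universe, n_query = len(universe), len(query)
    p_values = [
        float(hypergeom.sf(overlap - 1, m_universe, set_size, n_query))
        for _, _, set_size, overlap in rows
    ]
    adjusted = bh_adjust([min(p, 1.0) for p in p_values])
    results = [
        EnrichmentResult(
            set_id=set_id,
            description=description,
            overlap_count=overlap,
            query_size=n_query,
            set_size=set_size,
            universe_size=m_universe,
            p_value=min(p, 1.0),
            adjusted_p=q,
        )
        for (set_id, description, set_size, overlap), p, q in zip(
            rows, p_values, adjusted
        )
    ]
    results.sort(key=lambda r: (r.p_value, r.set_id))
    return results


def enrich_three_settings(
    global_net: GlobalNetwork,
    centrals: Iterable[str],
    collection: GeneSetCollection,
    universe: Iterable[str] | None = None,
) -> dict[str, list[EnrichmentResult]]:
    """Enrich the central proteins with each interactor class separately.

    The three queries are the centrals together with their CVD-only
    interactors, their CD-only interactors, and the interactors shared by
    both categories. The default universe is the Global Network node set.
    """
    centrals = set(centrals)
    universe = set(universe) if universe is not None else global_net.nodes
    if not centrals <= universe:
        raise ValueError("central proteins must lie in the universe")
    classes = classify_interactors(global_net, centrals)
    settings = {"cvd": "cvd_only", "cd": "cd_only", "both": "both"}
    out: dict[str, list[EnrichmentResult]] = {}
    for setting, klass in settings.items():
        interactors = {p for p, c in classes.items() if c == klass}
        query = (centrals | interactors) & universe
        out[setting] = hypergeom_enrich(query, universe, collection)
    return out
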