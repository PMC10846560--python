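"""Reading, writing and validation of interactomes, seed lists, category maps
and gene-set collections.

Node identifiers are opaque, case-sensitive gene symbols: no cross-database
identifier mapping is attempted, one symbol is one node. All interactomes are
simple undirected graphs — self-loop rows are dropped (and counted in the log)
and duplicate rows, including reversed duplicates, collapse to a single edge,
because the propagation algorithms assume a simple graph.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx

logger = logging.getLogger(__name__)

#: Disease categories recognized throughout the pipeline: cardiovascular
#: disease, cognitive dysfunction, oxidative stress.
CATEGORIES = ("CVD", "CD", "OS")


class FormatError(ValueError):
    """A file does not conform to its declared format."""


@dataclass(frozen=True)
class SeedSet:
    """A phenotype's literature-curated seed proteins.

    Seeds are the propagation sources: they are initialized at score 1 while
    every other node starts at 0.
    """

    phenotype_id: str
    category: str
    seeds: frozenset[str]

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(
                f"unknown category {self.category!r} for phenotype "
                f"{self.phenotype_id!r}; expected one of {CATEGORIES}"
            )
        if not self.seeds:
            raise ValueError(f"phenotype {self.phenotype_id!r} has no seeds")


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets (e.g. pathways) used for over-representation analysis.

    ``sets`` maps a unique set id to a ``(description, members)`` pair with
    de-duplicated members.
    """

    sets: Mapping[str, tuple[str, frozenset[str]]]

    def __len__(self) -> int:
        return len(self.sets)


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    suffix = path.suffix.lower().lstrip(".")
    return suffix if suffix in {"sif", "tsv", "graphml"} else "tsv"


def read_edge_list(path: str | Path, fmt: str | None = None) -> nx.Graph:
    """Read an undirected simple interactome from a SIF or two-column TSV file.

    SIF rows are ``source <relation> target [target ...]``; TSV rows are
    ``source<TAB>target``. Duplicate and reversed-duplicate rows collapse to
    one edge; self-loop rows are dropped and counted in the log.

    Raises
    ------
    FormatError
        On a malformed row (wrong column count, with its line number) or if
        the file yields an empty graph.
    """
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt not in {"sif", "tsv"}:
        raise FormatError(f"unsupported edge-list format {fmt!r}")
    graph = nx.Graph()
    self_loops = 0
    with path.open() as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t") if fmt == "tsv" else line.split()
            if fmt == "tsv":
                if len(fields) != 2:
                    raise FormatError(
                        f"{path}:{lineno}: expected 2 tab-separated columns, "
                        f"got {len(fields)}"
                    )
                pairs = [(fields[0], fields[1])]
            else:
                if len(fields) < 3:
                    raise FormatError(
                        f"{path}:{lineno}: SIF row needs 'source relation "
                        f"target...', got {len(fields)} column(s)"
                    )
                pairs = [(fields[0], target) for target in fields[2:]]
            for u, v in pairs:
                if u == v:
                    self_loops += 1
                    continue
                graph.add_edge(u, v)
    if self_loops:
        logger.info("dropped %d self-loop row(s) from %s", self_loops, path)
    if graph.number_of_edges() == 0:
        raise FormatError(f"{path}: no edges parsed; empty interactome")
    return graph


def read_category_map(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV mapping phenotype_id to disease category."""
    path = Path(path)
    mapping: dict[str, str] = {}
    with path.open() as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise FormatError(
                    f"{path}:{lineno}: expected 2 columns, got {len(fields)}"
                )
            phenotype, category = fields
            if category not in CATEGORIES:
                raise FormatError(
                    f"{path}:{lineno}: unknown category {category!r}"
                )
            mapping[phenotype] = category
    return mapping


def read_seed_file(
    path: str | Path,
    interactome: nx.Graph,
    category_map: Mapping[str, str] | None = None,
) -> list[SeedSet]:
    """Read per-phenotype seed genes from a 2- or 3-column TSV file.

    Columns are ``phenotype_id, gene[, category]``; when the third column is
    absent the category must come from ``category_map``. Genes absent from the
    interactome are excluded (and logged); phenotypes left with zero mapped
    seeds are dropped with a warning. Phenotype order follows first
    appearance in the file.
    """
    path = Path(path)
    order: list[str] = []
    genes: dict[str, set[str]] = {}
    categories: dict[str, str] = {}
    unmapped = 0
    with path.open() as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) not in (2, 3):
                raise FormatError(
                    f"{path}:{lineno}: expected 2 or 3 columns, got {len(fields)}"
                )
            phenotype, gene = fields[0], fields[1]
            if len(fields) == 3:
                category = fields[2]
                if category not in CATEGORIES:
                    raise FormatError(
                        f"{path}:{lineno}: unknown category {category!r}"
                    )
                previous = categories.setdefault(phenotype, category)
                if previous != category:
                    raise FormatError(
                        f"{path}:{lineno}: phenotype {phenotype!r} labelled "
                        f"both {previous!r} and {category!r}"
                    )
            if phenotype not in genes:
                genes[phenotype] = set()
                order.append(phenotype)
            if gene in interactome:
                genes[phenotype].add(gene)
            else:
                unmapped += 1
    if unmapped:
        logger.info("%d seed gene(s) absent from the interactome", unmapped)

    seed_sets: list[SeedSet] = []
    for phenotype in order:
        category = categories.get(phenotype)
        if category is None and category_map is not None:
            category = category_map.get(phenotype)
        if category is None:
            raise FormatError(
                f"no category for phenotype {phenotype!r}: provide a third "
                "column or a category map"
            )
        if not genes[phenotype]:
            logger.warning(
                "phenotype %r has no seeds mapped to the interactome; dropped",
                phenotype,
            )
            continue
        seed_sets.append(
            SeedSet(phenotype_id=phenotype, category=category,
                    seeds=frozenset(genes[phenotype]))
        )
    return seed_sets


def filter_phenotypes_by_seed_count(
    seed_sets: Sequence[SeedSet], min_seeds: int = 2
) -> list[SeedSet]:
    """Keep phenotypes with at least ``min_seeds`` mapped seed proteins.

    The default of 2 encodes the "more than one seed protein" rule used to
    discard phenotypes too thinly annotated for propagation. Input order is
    preserved.
    """
    if min_seeds < 1:
        raise ValueError("min_seeds must be >= 1")
    return [s for s in seed_sets if len(s.seeds) >= min_seeds]


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT gene-set file (set_id, description, members...)."""
    path = Path(path)
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    with path.open() as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT row needs id, description and at "
                    "least one member"
                )
            set_id, description = fields[0], fields[1]
            if set_id in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set id {set_id!r}")
            members = frozenset(m for m in fields[2:] if m)
            sets[set_id] = (description, members)
    return GeneSetCollection(sets=sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    """Write a gene-set collection in GMT format, rows and members sorted."""
    path = Path(path)
    with path.open("w") as handle:
        for set_id in sorted(collection.sets):
            description, members = collection.sets[set_id]
            handle.write("\t".join([set_id, description, *sorted(members)]) + "\n")


def sorted_copy(graph: nx.Graph) -> nx.Graph:
    """Copy a graph with nodes and edges inserted in sorted order.

    networkx serializers emit nodes in insertion order; normalizing here makes
    every file this package writes byte-reproducible.
    """
    out = nx.Graph()
    out.graph.update(graph.graph)
    for node in sorted(graph.nodes):
        out.add_node(node, **graph.nodes[node])
    for u, v in sorted(tuple(sorted(e)) for e in graph.edges):
        out.add_edge(u, v, **graph.edges[u, v])
    return out


def write_network(graph: nx.Graph, path: str | Path, fmt: str | None = None) -> None:
    """Write a network as sorted TSV/SIF edge rows or as GraphML.

    TSV and SIF rows are sorted lexicographically for reproducible diffs; node
    attributes survive only in GraphML. TSV/GraphML output round-trips:
    reading the written file reproduces the node set, edge set and (GraphML)
    attributes.
    """
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt == "graphml":
        nx.write_graphml(sorted_copy(graph), path)
        return
    if fmt not in {"tsv", "sif"}:
        raise FormatError(f"unsupported network format {fmt!r}")
    rows = sorted(tuple(sorted(edge)) for edge in graph.edges)
    with path.open("w") as handle:
        for u, v in rows:
            if fmt == "tsv":
                handle.write(f"{u}\t{v}\n")
            else:
                handle.write(f"{u} pp {v}\n")


def read_network(path: str | Path, fmt: str | None = None) -> nx.Graph:
    """Read a network written by :func:`write_network` (tsv, sif or graphml)."""
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt == "graphml":
        return nx.Graph(nx.read_graphml(path))
    return read_edge_list(path, fmt=fmt)


def restrict_seed_sets(
    seed_sets: Iterable[SeedSet], interactome: nx.Graph
) -> list[SeedSet]:
    """Restrict seed sets to interactome nodes, dropping emptied phenotypes."""
    out: list[SeedSet] = []
    for seed_set in seed_sets:
        mapped = frozenset(s for s in seed_set.seeds if s in interactome)
        if not mapped:
            logger.warning(
                "phenotype %r lost all seeds under restriction; dropped",
                seed_set.phenotype_id,
            )
            continue
        out.append(SeedSet(seed_set.phenotype_id, seed_set.category, mapped))
    return out
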