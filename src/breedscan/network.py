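"""Gene-interaction network modules scored by focus-gene overlap.

Around each breed's significant ("focus") genes, connected modules are grown
greedily on a user-supplied interaction graph and scored with the negative
log10 of the right-tail Fisher/hypergeometric p-value of their focus-gene
content — the higher the score, the less likely the module's focus density
arises by chance among the graph's genes.

The module-construction procedure is a documented stand-in for proprietary
network-generation algorithms: seed on the unassigned focus gene of highest
degree, then repeatedly absorb the neighbour adjacent to the most module
members (ties broken by degree, then lexicographic id) up to a size cap of
35 genes.  Module membership is therefore implementation-defined; only the
scoring formula is a reproducible statistic.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "NetworkModule",
    "read_edge_list",
    "build_modules",
    "score_module",
    "score_modules",
    "rank_and_count",
    "module_table",
]

SCORE_CAP = 300.0


@dataclass
class NetworkModule:
    """A connected gene subnetwork with its focus-gene content and score."""

    genes: tuple[str, ...]
    focus_genes: tuple[str, ...]
    score: float = float("nan")
    rank: int | None = None

    @property
    def focus_count(self) -> int:
        return len(self.focus_genes)

    @property
    def size(self) -> int:
        return len(self.genes)


def read_edge_list(path: str | Path) -> nx.Graph:
    """Undirected interaction graph from a two-column TSV; self-loops dropped."""
    edges = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if edges.shape[1] < 2:
        raise ValueError("edge list needs two columns")
    graph = nx.Graph()
    graph.add_edges_from(
        (a, b) for a, b in zip(edges[0], edges[1]) if a != b
    )
    return graph


def build_modules(
    graph: nx.Graph, focus_genes: Iterable[str], max_size: int = 35
) -> list[NetworkModule]:
    """Greedy seed-and-grow decomposition around the focus genes.

    Each gene ends up in at most one module; modules retaining fewer than two
    focus genes are discarded.  Fully deterministic through degree and
    lexicographic tie-breaking.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("empty interaction graph")
    if max_size < 1:
        raise ValueError("max_size must be positive")
    focus = set(focus_genes)
    present = focus & set(graph.nodes)
    absent = focus - present
    if absent:
        logger.info("build_modules: %d focus genes absent from the graph", len(absent))
    unassigned_focus = set(present)
    assigned: set[str] = set()
    modules: list[NetworkModule] = []
    while unassigned_focus:
        seed = min(unassigned_focus, key=lambda g: (-graph.degree(g), g))
        members: set[str] = {seed}
        while len(members) < max_size:
            adjacency: dict[str, int] = {}
            for gene in members:
                for nb in graph.neighbors(gene):
                    if nb not in members and nb not in assigned:
                        adjacency[nb] = adjacency.get(nb, 0) + 1
            if not adjacency:
                break
            pick = min(
                adjacency, key=lambda g: (-adjacency[g], -graph.degree(g), g)
            )
            members.add(pick)
        module_focus = members & present
        unassigned_focus -= members
        if len(module_focus) >= 2:
            assigned |= members
            modules.append(
                NetworkModule(
                    genes=tuple(sorted(members)),
                    focus_genes=tuple(sorted(module_focus)),
                )
            )
    return modules


def score_module(
    module: NetworkModule, focus_genes: Iterable[str], universe: Iterable[str]
) -> float:
    """``-log10`` right-tail hypergeometric p of the module's focus content.

    ``N`` is the universe (graph node set), ``K`` the focus genes in the
    universe, ``n`` the module size; the p-value is the probability of
    drawing at least ``focus_count`` focus genes in ``n`` draws.  Scores are
    capped at 300.
    """
    uni = set(universe)
    if module.size > len(uni):
        raise ValueError("module is larger than the universe")
    focus_in_uni = set(focus_genes) & uni
    fc = len(set(module.genes) & focus_in_uni)
    if fc == 0:
        return 0.0
    p = float(stats.hypergeom.sf(fc - 1, len(uni), len(focus_in_uni), module.size))
    if p <= 0.0:
        return SCORE_CAP
    return min(-math.log10(p), SCORE_CAP)


def score_modules(
    modules: Sequence[NetworkModule],
    focus_genes: Iterable[str],
    universe: Iterable[str],
) -> list[NetworkModule]:
    """Fill every module's score in place and return the list."""
    focus = set(focus_genes)
    uni = set(universe)
    for module in modules:
        module.score = score_module(module, focus, uni)
    return list(modules)


def rank_and_count(
    modules_per_breed: Mapping[str, Sequence[NetworkModule]],
    score_threshold: float = 2.0,
) -> pd.DataFrame:
    """Rank modules within each breed and rank breeds by scored-module count.

    Modules sort by descending score, with ties broken by larger size then
    gene ids; ranks 1..n are written back onto the modules.  The returned
    table reports both the total module count and the count at
    ``score >= score_threshold``, and orders breeds by the latter.
    """
    rows = []
    for breed, modules in modules_per_breed.items():
        ordered = sorted(modules, key=lambda m: (-m.score, -m.size, m.genes))
        for rank, module in enumerate(ordered, start=1):
            module.rank = rank
        n_scored = sum(m.score >= score_threshold for m in ordered)
        rows.append((breed, len(ordered), n_scored))
    table = pd.DataFrame(rows, columns=["breed", "n_modules", "n_above_threshold"])
    table = table.sort_values(
        ["n_above_threshold", "n_modules", "breed"],
        ascending=[False, False, True],
        ignore_index=True,
    )
    table["breed_rank"] = range(1, len(table) + 1)
    return table


def module_table(modules_per_breed: Mapping[str, Sequence[NetworkModule]]) -> pd.DataFrame:
    """Flat per-module report across breeds."""
    rows = []
    for breed, modules in modules_per_breed.items():
        for m in modules:
            rows.append(
                (breed, m.rank, m.score, m.focus_count, m.size, ";".join(m.genes))
            )
    return pd.DataFrame(
        rows, columns=["breed", "module_rank", "score", "focus_count", "size", "genes"]
    )
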