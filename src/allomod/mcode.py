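"""Molecular Complex Detection (MCODE) with a fixed 48-point parameter sweep.

MCODE finds locally dense regions of a network in three phases:

1. *Vertex weighting* — each node is scored by the density of the highest
   k-core of its closed neighborhood times that core number
   (core-clustering coefficient).  Nodes whose degree is below the degree
   cutoff score 0.
2. *Complex prediction* — seeds are taken in descending weight; a complex
   grows breadth-first from the seed, admitting a neighbor whose weight is
   within ``node_score_cutoff`` of the seed weight, up to ``max_depth`` hops.
   Nodes join at most one pre-fluff complex.
3. *Post-processing* — complexes with no 2-core are discarded; *haircut*
   iteratively strips nodes with within-complex degree < 2; *fluff* appends
   boundary neighbors whose closed-neighborhood density exceeds the fluff
   cutoff (fluffed nodes may be shared between complexes).

The sweep enumerates node score cutoff {0.0, 0.2, 0.3} x haircut {T,F} x
fluff {T,F} x max depth {100, 5, 4, 3} = 48 parameter combinations, with
degree cutoff 3, k-core 2 and loops excluded held fixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import product

import networkx as nx

from .graph_io import Module, StageNetwork

NODE_SCORE_CUTOFFS = (0.0, 0.2, 0.3)
HAIRCUT_VALUES = (True, False)
FLUFF_VALUES = (True, False)
MAX_DEPTHS = (100, 5, 4, 3)


@dataclass(frozen=True)
class MCODEParams:
    include_loops: bool = False
    degree_cutoff: int = 3
    node_score_cutoff: float = 0.0
    haircut: bool = True
    fluff: bool = False
    fluff_density_cutoff: float = 0.1
    k_core: int = 2
    max_depth: int = 100

    def __post_init__(self) -> None:
        if self.degree_cutoff < 2:
            raise ValueError("degree_cutoff must be >= 2")
        if not 0.0 <= self.node_score_cutoff <= 1.0:
            raise ValueError("node_score_cutoff must be in [0, 1]")
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")


def default_grid(fluff_density_cutoff: float = 0.1) -> list[MCODEParams]:
    """The fixed 3 x 2 x 2 x 4 = 48 parameter grid, in deterministic order
    (node score cutoff outermost, then haircut, fluff, max depth)."""
    return [
        MCODEParams(
            node_score_cutoff=nsc,
            haircut=hc,
            fluff=fl,
            fluff_density_cutoff=fluff_density_cutoff,
            max_depth=md,
        )
        for nsc, hc, fl, md in product(
            NODE_SCORE_CUTOFFS, HAIRCUT_VALUES, FLUFF_VALUES, MAX_DEPTHS
        )
    ]


@dataclass
class Partition:
    """Modules produced by one parameter combination, entropy filled later."""

    params: MCODEParams
    modules: list[Module]
    entropy: float | None = None
    grid_index: int | None = None


def _density(g: nx.Graph) -> float:
    # loops excluded (include_loops is false throughout)
    n = g.number_of_nodes()
    if n < 2:
        return 0.0
    return 2.0 * g.number_of_edges() / (n * (n - 1))


def _highest_kcore(g: nx.Graph) -> tuple[int, nx.Graph]:
    """Return (k, subgraph) for the highest-k non-empty k-core of ``g``."""
    core_numbers = nx.core_number(g)
    k = max(core_numbers.values(), default=0)
    nodes = [v for v, c in core_numbers.items() if c >= k]
    return k, g.subgraph(nodes)


def vertex_weights(network: StageNetwork, degree_cutoff: int = 3) -> dict[str, float]:
    """Core-clustering-coefficient weight for every node.

    weight(v) = k * density(highest k-core of closed neighborhood of v);
    0 for nodes with degree below the cutoff.
    """
    g = network.to_networkx()
    weights: dict[str, float] = {}
    for v in g.nodes():
        if g.degree(v) < degree_cutoff:
            weights[v] = 0.0
            continue
        closed = g.subgraph(list(g.neighbors(v)) + [v])
        k, core = _highest_kcore(closed)
        weights[v] = k * _density(core)
    return weights


def _haircut(g: nx.Graph, members: set[str]) -> set[str]:
    """Iteratively remove nodes with within-complex degree < 2 (to fixed point)."""
    members = set(members)
    while True:
        sub = g.subgraph(members)
        trim = {v for v in members if sub.degree(v) < 2}
        if not trim:
            return members
        members -= trim


def _closed_neighborhood_density(g: nx.Graph, v: str) -> float:
    return _density(g.subgraph(list(g.neighbors(v)) + [v]))


def find_complexes(network: StageNetwork, params: MCODEParams) -> list[Module]:
    """Run the three MCODE phases and return modules in deterministic order.

    Seed ties at equal weight break by lexicographically smallest gene symbol.
    Output is sorted by (size desc, lexicographically smallest node).  Fluffed
    nodes are not marked visited and may appear in several modules.
    """
    g = network.to_networkx()
    weights = vertex_weights(network, params.degree_cutoff)
    # descending weight, lexicographic tie-break
    seed_order = sorted(g.nodes(), key=lambda v: (-weights[v], v))
    visited: set[str] = set()
    complexes: list[set[str]] = []

    for seed in seed_order:
        if seed in visited:
            continue
        threshold = weights[seed] * (1.0 - params.node_score_cutoff)
        members = {seed}
        frontier = [seed]
        depth = 0
        while frontier and depth < params.max_depth:
            nxt: list[str] = []
            for v in frontier:
                for u in g.neighbors(v):
                    if u in visited or u in members:
                        continue
                    if weights[u] >= threshold:
                        members.add(u)
                        nxt.append(u)
            frontier = nxt
            depth += 1
        visited |= members  # pre-fluff complexes are node-disjoint
        complexes.append(members)

    modules: list[Module] = []
    for members in complexes:
        sub = g.subgraph(members)
        # discard complexes not containing a k-core (k_core fixed at 2)
        k_max = max(nx.core_number(sub).values(), default=0)
        if k_max < params.k_core:
            continue
        if params.haircut:
            members = _haircut(g, members)
            if not members:
                continue
        if params.fluff:
            fluffed = set(members)
            for v in sorted(members):
                for u in sorted(g.neighbors(v)):
                    if u in visited or u in fluffed:
                        continue
                    if _closed_neighborhood_density(g, u) > params.fluff_density_cutoff:
                        fluffed.add(u)
            members = fluffed
        if len(members) >= 2:
            modules.append(Module.induced("tmp", network, members))

    modules.sort(key=lambda m: (-m.size, min(m.nodes)))
    return [
        replace(m, module_id=f"{network.stage_label}{i}")
        for i, m in enumerate(modules, start=1)
    ]


def run_grid(
    network: StageNetwork,
    min_module_size: int = 4,
    grid: list[MCODEParams] | None = None,
) -> list[Partition]:
    """Run every grid point; drop modules below ``min_module_size`` (the
    reporting filter keeps modules with >= 4 nodes)."""
    if grid is None:
        grid = default_grid()
    partitions = []
    for i, params in enumerate(grid):
        mods = [m for m in find_complexes(network, params) if m.size >= min_module_size]
        partitions.append(Partition(params=params, modules=mods, grid_index=i))
    return partitions
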