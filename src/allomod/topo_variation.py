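"""Topological characterization of oncogenic module associations.

Each partially overlapping module pair has (a) an *overlap structure* — the
shape of the shared subgraph that bridges the two modules — and (b) a *change
type* describing how much of each module lies outside the overlap.

Overlap structures (checked in precedence order):

* fully_contained — one module's nodes and edges are subsets of the other's
* triangular      — the shared subgraph is exactly 3 nodes and 3 edges
* multiedge       — more than 3 shared nodes and >= 3 shared edges
* one_edge        — exactly one shared edge (two shared nodes)

A shared subgraph matching none of these literally (e.g. a 3-node path) falls
back to ``multiedge`` so that every valid pair receives exactly one label;
the strict multiedge reading is available via ``strict=True``.

Change types threshold the per-side counts of non-shared nodes at 3:
both deltas < 3 -> node_node; exactly one delta >= 3 -> node_module;
both >= 3 -> module_module.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from itertools import combinations

from .am_taxonomy import AMAssociation
from .graph_io import Edge, Module

NODE_MODULE_THRESHOLD = 3


class OverlapKind(str, Enum):
    FULLY_CONTAINED = "fully_contained"
    ONE_EDGE = "one_edge"
    TRIANGULAR = "triangular"
    MULTIEDGE = "multiedge"


class ChangeKind(str, Enum):
    NODE_NODE = "node_node"
    NODE_MODULE = "node_module"
    MODULE_MODULE = "module_module"


@dataclass(frozen=True)
class OverlapStructure:
    kind: OverlapKind
    shared_nodes: frozenset[str]
    shared_edges: frozenset[Edge]


@dataclass(frozen=True)
class ChangeType:
    kind: ChangeKind
    delta_a: int
    delta_b: int


def overlap_structure_pair(a: Module, b: Module, strict: bool = False) -> OverlapStructure:
    """Label the shared subgraph of a partially overlapping module pair."""
    shared_nodes = a.nodes & b.nodes
    shared_edges = a.edges & b.edges
    if not shared_edges:
        raise ValueError(
            f"{a.module_id}/{b.module_id}: empty shared edge set is not a valid "
            "partial overlap (node-only overlaps are disease-exclusive)"
        )
    contained = (a.nodes <= b.nodes and a.edges <= b.edges) or (
        b.nodes <= a.nodes and b.edges <= a.edges
    )
    if contained:
        kind = OverlapKind.FULLY_CONTAINED
    elif len(shared_nodes) == 3 and len(shared_edges) == 3:
        kind = OverlapKind.TRIANGULAR
    elif len(shared_nodes) > 3 and len(shared_edges) >= 3:
        kind = OverlapKind.MULTIEDGE
    elif len(shared_edges) == 1:
        kind = OverlapKind.ONE_EDGE
    elif strict:
        raise ValueError(
            f"{a.module_id}/{b.module_id}: shared subgraph "
            f"({len(shared_nodes)} nodes, {len(shared_edges)} edges) matches no "
            "strict overlap category"
        )
    else:
        kind = OverlapKind.MULTIEDGE  # fallback for in-between shapes
    return OverlapStructure(kind, frozenset(shared_nodes), frozenset(shared_edges))


def change_type_pair(a: Module, b: Module) -> ChangeType:
    """Classify the non-overlapping parts by node-count deltas."""
    delta_a = len(a.nodes - b.nodes)
    delta_b = len(b.nodes - a.nodes)
    big_a = delta_a >= NODE_MODULE_THRESHOLD
    big_b = delta_b >= NODE_MODULE_THRESHOLD
    if big_a and big_b:
        kind = ChangeKind.MODULE_MODULE
    elif big_a or big_b:
        kind = ChangeKind.NODE_MODULE
    else:
        kind = ChangeKind.NODE_NODE
    return ChangeType(kind, delta_a, delta_b)


def overlap_structure(assoc: AMAssociation, strict: bool = False) -> dict[tuple[str, str], OverlapStructure]:
    """Overlap structure per ordered stage pair of the association.

    Pairs are evaluated in progression order (adjacent pairs plus the
    first-to-terminal pair for triples).
    """
    out: dict[tuple[str, str], OverlapStructure] = {}
    for a, b in combinations(assoc.members, 2):
        out[(a.module_id, b.module_id)] = overlap_structure_pair(a, b, strict=strict)
    return out


def change_type(assoc: AMAssociation) -> dict[tuple[str, str], ChangeType]:
    return {
        (a.module_id, b.module_id): change_type_pair(a, b)
        for a, b in combinations(assoc.members, 2)
    }
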