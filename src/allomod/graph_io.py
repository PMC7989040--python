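"""Stage-network and module data model plus readers/writers for standard formats.

A *stage network* is the undirected gene graph associated with one pathological
stage of a progressive disease (e.g. chronic hepatitis B -> cirrhosis ->
hepatocellular carcinoma).  A *module* is a dense subgraph detected within one
stage network; cross-stage comparison of modules is the core of the package.

Gene symbols are case-normalized to upper case throughout, because public gene
annotations mix cases (``cyp1a2`` vs ``CYP1A2``).  Edges are unordered pairs:
``(a, b)`` and ``(b, a)`` denote the same interaction.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

logger = logging.getLogger(__name__)

Edge = tuple[str, str]

NETWORK_FORMATS = ("sif", "edgelist", "graphml")


def canonical_edge(a: str, b: str) -> Edge:
    """Orientation-free edge identity: sorted unordered pair."""
    return (a, b) if a <= b else (b, a)


def _norm(symbol: str) -> str:
    return symbol.strip().upper()


class ParseError(ValueError):
    """Raised when an input file does not follow its declared dialect."""


@dataclass(frozen=True)
class StageNetwork:
    """Undirected simple gene graph for one disease stage.

    Invariants: no self-loops, no duplicate edges, every edge endpoint is a
    node, edge identity is symmetric.
    """

    stage_label: str
    nodes: frozenset[str]
    edges: frozenset[Edge]

    def __post_init__(self) -> None:
        for a, b in self.edges:
            if a == b:
                raise ValueError(f"self-loop on {a!r}")
            if (a, b) != canonical_edge(a, b):
                raise ValueError(f"non-canonical edge ({a!r}, {b!r})")
            if a not in self.nodes or b not in self.nodes:
                raise ValueError(f"edge ({a!r}, {b!r}) endpoint missing from nodes")

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(sorted(self.nodes))
        g.add_edges_from(sorted(self.edges))
        return g

    @classmethod
    def from_edges(
        cls, stage_label: str, edges: Iterable[tuple[str, str]], extra_nodes: Iterable[str] = ()
    ) -> "StageNetwork":
        """Build a network from raw edge records, enforcing all invariants.

        Self-loops and duplicate (either-orientation) records are dropped; the
        number dropped is logged.
        """
        nodes: set[str] = {_norm(n) for n in extra_nodes}
        edge_set: set[Edge] = set()
        n_loops = n_dups = 0
        for a, b in edges:
            a, b = _norm(a), _norm(b)
            nodes.add(a)
            nodes.add(b)
            if a == b:
                n_loops += 1
                continue
            e = canonical_edge(a, b)
            if e in edge_set:
                n_dups += 1
            else:
                edge_set.add(e)
        if n_loops or n_dups:
            logger.info(
                "stage %s: dropped %d self-loop and %d duplicate edge records",
                stage_label, n_loops, n_dups,
            )
        return cls(stage_label=stage_label, nodes=frozenset(nodes), edges=frozenset(edge_set))


@dataclass(frozen=True)
class Module:
    """A detected module: named node set plus its retained induced edges."""

    module_id: str
    stage_label: str
    nodes: frozenset[str]
    edges: frozenset[Edge]

    def __post_init__(self) -> None:
        if len(self.nodes) < 2:
            raise ValueError(f"module {self.module_id!r}: needs >= 2 nodes")
        for a, b in self.edges:
            if a == b or (a, b) != canonical_edge(a, b):
                raise ValueError(f"module {self.module_id!r}: bad edge ({a!r}, {b!r})")
            if a not in self.nodes or b not in self.nodes:
                raise ValueError(f"module {self.module_id!r}: edge endpoint outside module")

    @classmethod
    def induced(cls, module_id: str, network: StageNetwork, nodes: Iterable[str]) -> "Module":
        node_set = frozenset(_norm(n) for n in nodes)
        edges = frozenset(e for e in network.edges if e[0] in node_set and e[1] in node_set)
        return cls(module_id=module_id, stage_label=network.stage_label,
                   nodes=node_set, edges=edges)

    @property
    def size(self) -> int:
        return len(self.nodes)


def read_network(path: str | Path, format: str, stage_label: str) -> StageNetwork:
    """Read a stage network from SIF, 2-column edge-list TSV, or GraphML.

    The SIF interaction-type field is ignored for topology; all formats yield
    an undirected simple graph with upper-cased gene symbols.
    """
    path = Path(path)
    if format not in NETWORK_FORMATS:
        raise ValueError(f"unknown format {format!r}; expected one of {NETWORK_FORMATS}")
    if format == "graphml":
        g = nx.read_graphml(path)
        return StageNetwork.from_edges(
            stage_label, ((str(a), str(b)) for a, b in g.edges()),
            extra_nodes=(str(n) for n in g.nodes()),
        )

    edges: list[tuple[str, str]] = []
    isolated: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if format == "sif":
                # node [type node ...]; a 1-field line declares an isolated node
                if len(fields) == 1:
                    isolated.append(fields[0])
                elif len(fields) >= 3:
                    edges.extend((fields[0], t) for t in fields[2:])
                else:
                    raise ParseError(f"{path}:{lineno}: SIF line has 2 fields: {line!r}")
            else:  # edgelist
                if len(fields) < 2:
                    raise ParseError(f"{path}:{lineno}: edge list needs 2 columns: {line!r}")
                edges.append((fields[0], fields[1]))
    return StageNetwork.from_edges(stage_label, edges, extra_nodes=isolated)


def write_network(network: StageNetwork, path: str | Path, format: str = "sif") -> None:
    path = Path(path)
    if format == "sif":
        with open(path, "w") as fh:
            connected = {n for e in network.edges for n in e}
            for a, b in sorted(network.edges):
                fh.write(f"{a}\tpp\t{b}\n")
            for n in sorted(network.nodes - connected):
                fh.write(f"{n}\n")
    elif format == "edgelist":
        with open(path, "w") as fh:
            for a, b in sorted(network.edges):
                fh.write(f"{a}\t{b}\n")
    elif format == "graphml":
        nx.write_graphml(network.to_networkx(), path)
    else:
        raise ValueError(f"unknown format {format!r}")


def read_gmt(path: str | Path) -> dict[str, frozenset[str]]:
    """Read gene sets from a GMT file (term, description, member genes).

    Duplicate terms are unioned with a logged warning; genes are upper-cased
    and deduplicated per term.
    """
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: GMT line needs >= 3 fields: {line!r}")
            term = fields[0].strip()
            genes = {_norm(g) for g in fields[2:] if g.strip()}
            if term in sets:
                logger.warning("%s:%d: duplicate GMT term %r unioned", path, lineno, term)
                sets[term] |= genes
            else:
                sets[term] = genes
    return {t: frozenset(g) for t, g in sets.items()}


def write_modules(modules: Iterable[Module], path: str | Path) -> None:
    """Write modules as a JSON array (stage, id, sorted nodes, sorted edges)."""
    records = [
        {
            "stage": m.stage_label,
            "id": m.module_id,
            "nodes": sorted(m.nodes),
            "edges": [list(e) for e in sorted(m.edges)],
        }
        for m in modules
    ]
    with open(path, "w") as fh:
        json.dump(records, fh, indent=1)
        fh.write("\n")


def read_modules(path: str | Path) -> list[Module]:
    with open(path) as fh:
        records = json.load(fh)
    return [
        Module(
            module_id=r["id"],
            stage_label=r["stage"],
            nodes=frozenset(r["nodes"]),
            edges=frozenset(canonical_edge(a, b) for a, b in r["edges"]),
        )
        for r in records
    ]


def read_expression(expr_path: str | Path, labels_path: str | Path | None = None):
    """Read an expression matrix (rows = samples, columns = genes) and labels.

    Expression CSV: first column sample id, header gene symbols.  Metadata CSV:
    sample id, class.  Returns ``(DataFrame, Series)``; the label Series is
    aligned to the expression rows.  Gene symbols are upper-cased; missing
    values are an error.
    """
    import pandas as pd

    expr = pd.read_csv(expr_path, index_col=0)
    expr.columns = [_norm(c) for c in expr.columns]
    if expr.isna().any().any():
        raise ValueError(f"{expr_path}: expression matrix contains missing values")
    if len(set(expr.columns)) != len(expr.columns):
        raise ValueError(f"{expr_path}: duplicate gene symbols after case-normalization")
    labels = None
    if labels_path is not None:
        meta = pd.read_csv(labels_path, index_col=0)
        labels = meta.iloc[:, 0].reindex(expr.index)
        if labels.isna().any():
            missing = list(labels[labels.isna()].index[:5])
            raise ValueError(f"{labels_path}: samples without class label, e.g. {missing}")
    return expr, labels
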