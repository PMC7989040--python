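"""Seeded synthetic fixtures with planted ground truth.

Two generators make every pipeline stage testable without external data:

* ``gen_stage_networks`` builds three stage networks containing planted
  cliques arranged to realize each allosteric-module class exactly —
  identical cliques (CAM), partially overlapping cliques confined to the
  first two stages (TAM), overlaps involving the terminal stage with a chosen
  bridge shape (OAM), and stage-exclusive cliques (DEM) — on a sparse
  background.  The background defaults to an acyclic (spanning-forest)
  thinning of an Erdos-Renyi draw: a background cycle would itself be a
  2-core and would surface as a spurious module, so acyclicity keeps the
  planted truth table exhaustive.
* ``gen_expression`` draws class-labeled multivariate-normal expression with
  requested gene-gene correlations and class-separating mean shifts around a
  positive baseline intensity.

Everything is deterministic under the configured seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

from .graph_io import Module, StageNetwork, canonical_edge

OAM_OVERLAPS = ("one_edge", "triangular", "multiedge", "fully_contained")
_OVERLAP_SHARED = {"one_edge": 2, "triangular": 3, "multiedge": 4}


# --------------------------------------------------------------------------
# planting directives
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantCAM:
    """Identical clique planted into two or three stages."""
    size: int = 5
    stages: tuple[int, ...] = (0, 1)


@dataclass(frozen=True)
class PlantTAM:
    """Partially overlapping cliques in stages 1-2 with a node-Jaccard target;
    no overlap with the terminal stage."""
    size: int = 5
    jaccard: float = 0.4


@dataclass(frozen=True)
class PlantOAM:
    """Partial overlap involving the terminal stage with a chosen bridge shape."""
    overlap: str = "one_edge"
    size_a: int = 6
    size_b: int = 6
    stages: tuple[int, int] = (1, 2)
    contained_size: int = 4  # only for fully_contained


@dataclass(frozen=True)
class PlantDEM:
    """Stage-exclusive clique."""
    size: int = 5
    stage: int = 0


Directive = PlantCAM | PlantTAM | PlantOAM | PlantDEM


@dataclass
class StageNetConfig:
    n_background_nodes: int = 40
    background_edge_prob: float = 0.03
    planted: tuple[Directive, ...] = (
        PlantCAM(), PlantTAM(), PlantOAM(), PlantDEM(), PlantDEM(stage=2),
    )
    stage_labels: tuple[str, str, str] = ("CHB", "CIRRHOSIS", "HCC")
    acyclic_background: bool = True
    seed: int = 0


def _clique_edges(nodes: Sequence[str]) -> set[tuple[str, str]]:
    return {canonical_edge(a, b) for a, b in combinations(nodes, 2)}


def _tam_shared_count(size: int, target: float) -> int:
    """Shared-node count m for two size-s cliques so the node Jaccard
    m / (2s - m) is closest to the target (constructive, not sampled)."""
    best = None
    for m in range(2, size):
        j = m / (2 * size - m)
        dev = abs(j - target)
        if best is None or dev < best[0]:
            best = (dev, m, j)
    if best is None or best[0] > 0.05:
        feasible = [round(m / (2 * size - m), 3) for m in range(2, size)]
        raise ValueError(
            f"TAM Jaccard target {target} infeasible within 0.05 for clique size "
            f"{size}; feasible targets: {feasible} (use a larger size)"
        )
    return best[1]


def _expected_change_kind(delta_a: int, delta_b: int) -> str:
    big_a, big_b = delta_a >= 3, delta_b >= 3
    if big_a and big_b:
        return "module_module"
    if big_a or big_b:
        return "node_module"
    return "node_node"


def gen_stage_networks(cfg: StageNetConfig):
    """Generate three stage networks and the machine-readable truth table.

    Returns ``(networks, truth)`` where ``networks`` is a tuple of three
    StageNetworks and ``truth`` a list of dicts, one per directive, each with
    the planted type, stage indices, per-stage node sets, and the expected
    similarity / topology labels implied by the construction.
    """
    rng = np.random.default_rng(cfg.seed)
    per_stage_edges: list[set[tuple[str, str]]] = [set(), set(), set()]
    per_stage_nodes: list[set[str]] = [set(), set(), set()]
    truth: list[dict] = []

    def plant(stage: int, nodes: Sequence[str]) -> None:
        if per_stage_nodes[stage] & set(nodes):
            raise ValueError(
                f"planted modules collide within stage {stage}: {sorted(set(nodes) & per_stage_nodes[stage])}"
            )
        per_stage_nodes[stage] |= set(nodes)
        per_stage_edges[stage] |= _clique_edges(nodes)

    for k, d in enumerate(cfg.planted):
        ns = f"P{k}"  # reserved per-directive namespace
        if isinstance(d, PlantCAM):
            if d.size < 4:
                raise ValueError("CAM clique size must be >= 4 for detectability")
            nodes = [f"{ns}N{i}" for i in range(d.size)]
            for s in d.stages:
                plant(s, nodes)
            truth.append({
                "type": "CAM", "stages": tuple(d.stages),
                "nodes": {s: frozenset(nodes) for s in d.stages},
                "s_n": 1.0, "s_e": 1.0,
            })
        elif isinstance(d, PlantTAM):
            if d.size < 4:
                raise ValueError("TAM clique size must be >= 4")
            m = _tam_shared_count(d.size, d.jaccard)
            shared = [f"{ns}S{i}" for i in range(m)]
            a = shared + [f"{ns}A{i}" for i in range(d.size - m)]
            b = shared + [f"{ns}B{i}" for i in range(d.size - m)]
            plant(0, a)
            plant(1, b)
            n_union = 2 * d.size - m
            e_shared = m * (m - 1) // 2
            e_each = d.size * (d.size - 1) // 2
            truth.append({
                "type": "TAM", "stages": (0, 1),
                "nodes": {0: frozenset(a), 1: frozenset(b)},
                "s_n": m / n_union,
                "s_e": e_shared / (2 * e_each - e_shared),
            })
        elif isinstance(d, PlantOAM):
            if d.overlap not in OAM_OVERLAPS:
                raise ValueError(f"unknown OAM overlap type {d.overlap!r}")
            i, j = d.stages
            if j != 2 or i not in (0, 1):
                raise ValueError("OAM stage pair must involve the terminal stage: (0,2) or (1,2)")
            if d.overlap == "fully_contained":
                if not 4 <= d.contained_size < d.size_b:
                    raise ValueError("fully_contained needs 4 <= contained_size < size_b")
                outer = [f"{ns}N{t}" for t in range(d.size_b)]
                inner = outer[: d.contained_size]
                plant(i, inner)
                plant(j, outer)
                a_nodes, b_nodes = inner, outer
                m = d.contained_size
                e_shared = m * (m - 1) // 2
                e_union = d.size_b * (d.size_b - 1) // 2
            else:
                m = _OVERLAP_SHARED[d.overlap]
                if d.size_a <= m or d.size_b <= m or min(d.size_a, d.size_b) < 4:
                    raise ValueError(
                        f"OAM {d.overlap} needs clique sizes > {m} shared nodes and >= 4"
                    )
                shared = [f"{ns}S{t}" for t in range(m)]
                a_nodes = shared + [f"{ns}A{t}" for t in range(d.size_a - m)]
                b_nodes = shared + [f"{ns}B{t}" for t in range(d.size_b - m)]
                plant(i, a_nodes)
                plant(j, b_nodes)
                e_shared = m * (m - 1) // 2
                e_union = (d.size_a * (d.size_a - 1) // 2
                           + d.size_b * (d.size_b - 1) // 2 - e_shared)
            delta_a = len(set(a_nodes) - set(b_nodes))
            delta_b = len(set(b_nodes) - set(a_nodes))
            truth.append({
                "type": "OAM", "stages": (i, j),
                "nodes": {i: frozenset(a_nodes), j: frozenset(b_nodes)},
                "s_n": m / len(set(a_nodes) | set(b_nodes)),
                "s_e": e_shared / e_union,
                "overlap_structure": d.overlap,
                "change_type": _expected_change_kind(delta_a, delta_b),
                "deltas": (delta_a, delta_b),
            })
        elif isinstance(d, PlantDEM):
            if d.size < 4:
                raise ValueError("DEM clique size must be >= 4")
            nodes = [f"{ns}N{i}" for i in range(d.size)]
            plant(d.stage, nodes)
            truth.append({
                "type": "DEM", "stages": (d.stage,),
                "nodes": {d.stage: frozenset(nodes)},
                "reason": "no_overlap",
            })
        else:  # pragma: no cover
            raise TypeError(f"unknown directive {d!r}")

    # sparse background, disjoint namespace, per stage
    bg_nodes = [f"BG{i}" for i in range(cfg.n_background_nodes)]
    networks = []
    for s in range(3):
        edges = set(per_stage_edges[s])
        nodes = set(per_stage_nodes[s]) | set(bg_nodes)
        bg_edges = [
            canonical_edge(a, b)
            for a, b in combinations(bg_nodes, 2)
            if rng.random() < cfg.background_edge_prob
        ]
        if cfg.acyclic_background:
            # spanning-forest thinning: keep only cycle-free edges (union-find)
            parent = {n: n for n in bg_nodes}

            def find(x: str) -> str:
                while parent[x] != x:
                    parent[x] = parent[parent[x]]
                    x = parent[x]
                return x

            kept = []
            for a, b in bg_edges:
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[ra] = rb
                    kept.append((a, b))
            bg_edges = kept
        edges |= set(bg_edges)
        networks.append(
            StageNetwork(
                stage_label=cfg.stage_labels[s],
                nodes=frozenset(nodes),
                edges=frozenset(edges),
            )
        )
    return tuple(networks), truth


def planted_modules(
    networks: Sequence[StageNetwork], truth: list[dict]
) -> tuple[list[Module], list[Module], list[Module]]:
    """Materialize the planted node sets as Module objects per stage
    (deterministic ids), bypassing detection for closed-loop taxonomy tests."""
    out: tuple[list[Module], list[Module], list[Module]] = ([], [], [])
    seen: list[set[frozenset[str]]] = [set(), set(), set()]
    for entry in truth:
        for s, nodes in sorted(entry["nodes"].items()):
            if nodes in seen[s]:
                continue
            seen[s].add(nodes)
            out[s].append(
                Module.induced(
                    f"{networks[s].stage_label}{len(out[s]) + 1}", networks[s], nodes
                )
            )
    return out


def write_truth(truth: list[dict], path) -> None:
    """Serialize a truth table to JSON (node sets become sorted lists)."""
    import json

    doc = []
    for entry in truth:
        e = dict(entry)
        e["stages"] = list(e["stages"])
        e["nodes"] = {str(s): sorted(nodes) for s, nodes in e["nodes"].items()}
        if "deltas" in e:
            e["deltas"] = list(e["deltas"])
        doc.append(e)
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")


# --------------------------------------------------------------------------
# expression generator
# --------------------------------------------------------------------------

@dataclass
class ExprConfig:
    n_samples: tuple[int, int] = (100, 100)  # per class: (negative, positive)
    n_genes: int = 20
    planted_pairs: tuple[tuple[str, str, float], ...] = ()
    planted_effects: tuple[tuple[str, float], ...] = ()  # standardized mean shift in the positive class
    baseline_mean: float = 10.0
    noise_sd: float = 1.0
    classes: tuple[str, str] = ("NON_TUMOR", "TUMOR")
    lognormal: bool = False
    seed: int = 0


def _gene_names(n: int) -> list[str]:
    return [f"G{i + 1:03d}" for i in range(n)]


def gen_expression(cfg: ExprConfig) -> tuple[pd.DataFrame, pd.Series]:
    """Class-labeled expression matrix with planted correlations and shifts.

    Each class is multivariate normal around a positive baseline intensity;
    planted pairs impose the requested Pearson correlation (identical in both
    classes), planted effects shift the positive-class mean by the stated
    number of noise standard deviations.  A non-positive-semidefinite
    correlation request raises with a nearest-PSD hint.  Returns
    ``(expression DataFrame, label Series)``.
    """
    genes = _gene_names(cfg.n_genes)
    idx = {g: i for i, g in enumerate(genes)}
    corr = np.eye(cfg.n_genes)
    for a, b, rho in cfg.planted_pairs:
        a, b = a.upper(), b.upper()
        if a not in idx or b not in idx:
            raise ValueError(f"planted pair ({a}, {b}) names an unknown gene")
        if not -1.0 < rho < 1.0:
            raise ValueError(f"planted correlation must be in (-1, 1), got {rho}")
        corr[idx[a], idx[b]] = corr[idx[b], idx[a]] = rho
    eigvals = np.linalg.eigvalsh(corr)
    if eigvals.min() < -1e-10:
        clipped = np.clip(eigvals, 0.0, None)
        raise ValueError(
            "requested correlation set is not positive semidefinite "
            f"(min eigenvalue {eigvals.min():.4f}); nearest PSD matrix would "
            f"rescale the spectrum to {np.round(clipped, 3).tolist()}"
        )
    cov = corr * cfg.noise_sd ** 2

    shift = np.zeros(cfg.n_genes)
    for g, s in cfg.planted_effects:
        g = g.upper()
        if g not in idx:
            raise ValueError(f"planted effect names an unknown gene {g}")
        shift[idx[g]] = s * cfg.noise_sd

    rng = np.random.default_rng(cfg.seed)
    blocks, labels = [], []
    for cls, n, mean in (
        (cfg.classes[0], cfg.n_samples[0], np.full(cfg.n_genes, cfg.baseline_mean)),
        (cfg.classes[1], cfg.n_samples[1], np.full(cfg.n_genes, cfg.baseline_mean) + shift),
    ):
        x = rng.multivariate_normal(mean, cov, size=n, method="cholesky" if eigvals.min() > 1e-10 else "svd")
        blocks.append(x)
        labels.extend([cls] * n)
    x = np.vstack(blocks)
    if cfg.lognormal:
        x = np.exp(x / cfg.baseline_mean) * cfg.baseline_mean
    samples = [f"S{i + 1:04d}" for i in range(len(labels))]
    expr = pd.DataFrame(x, index=samples, columns=genes)
    return expr, pd.Series(labels, index=samples, name="class")
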