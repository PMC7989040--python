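"""Minimum-entropy selection among the 48 MCODE parameter combinations.

The sweep over detection parameters yields 48 candidate module partitions;
one is selected by a network-entropy criterion (lower entropy = more ordered,
more sharply structured modules).  The default per-module entropy is the
Shannon entropy of the internal-degree distribution, normalized by its
maximum: with internal degrees d_i and p_i = d_i / sum_j d_j,

    H(m) = -sum_i p_i log2 p_i / log2 |nodes(m)|     in [0, 1].

A clique scores exactly 1 (uniform p); a hub-dominated star scores lower.
The partition score is the module-size-weighted mean of module entropies.
Alternative strategies (unnormalized degree entropy; entropy of the
module-size distribution) are selectable by name.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .graph_io import Module
from .mcode import MCODEParams, Partition

STRATEGIES = ("degree-entropy", "degree-entropy-unnormalized", "size-distribution")


def module_entropy(module: Module, normalized: bool = True) -> float:
    """Entropy of the module's internal-degree distribution (bits).

    Zero-edge modules return 0 by convention; with ``normalized`` the value is
    divided by log2(n) so any clique scores exactly 1.
    """
    if not module.edges:
        return 0.0
    degree: dict[str, int] = {v: 0 for v in module.nodes}
    for a, b in module.edges:
        degree[a] += 1
        degree[b] += 1
    total = sum(degree.values())
    h = -sum(
        (d / total) * math.log2(d / total) for d in degree.values() if d > 0
    )
    if not normalized:
        return h
    n = len(module.nodes)
    return h / math.log2(n) if n > 1 else 0.0


def partition_entropy(partition: Partition, strategy: str = "degree-entropy") -> float:
    """Total entropy of a partition under the named strategy.

    degree-entropy strategies: size-weighted mean of per-module entropies.
    size-distribution: -sum (n_m/N) log2 (n_m/N) over module sizes.
    Empty partitions score 0.
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown entropy strategy {strategy!r}; expected one of {STRATEGIES}")
    mods = partition.modules
    if not mods:
        return 0.0
    if strategy in ("degree-entropy", "degree-entropy-unnormalized"):
        normalized = strategy == "degree-entropy"
        total_size = sum(m.size for m in mods)
        return sum(m.size * module_entropy(m, normalized) for m in mods) / total_size
    if strategy == "size-distribution":
        total = sum(m.size for m in mods)
        return -sum((m.size / total) * math.log2(m.size / total) for m in mods)
    raise ValueError(f"unknown entropy strategy {strategy!r}; expected one of {STRATEGIES}")


@dataclass
class EntropyReport:
    params: MCODEParams
    grid_index: int
    n_modules: int
    mean_module_size: float
    per_module_entropy: dict[str, float]
    total_entropy: float


def score_partitions(
    partitions: list[Partition], strategy: str = "degree-entropy"
) -> list[EntropyReport]:
    """Attach entropies to every partition and emit per-grid-point reports."""
    reports = []
    for i, p in enumerate(partitions):
        idx = p.grid_index if p.grid_index is not None else i
        p.entropy = partition_entropy(p, strategy)
        normalized = strategy != "degree-entropy-unnormalized"
        per_mod = {
            m.module_id: module_entropy(m, normalized) for m in p.modules
        }
        sizes = [m.size for m in p.modules]
        reports.append(
            EntropyReport(
                params=p.params,
                grid_index=idx,
                n_modules=len(p.modules),
                mean_module_size=sum(sizes) / len(sizes) if sizes else 0.0,
                per_module_entropy=per_mod,
                total_entropy=p.entropy,
            )
        )
    return reports


def select_min_entropy(
    partitions: list[Partition], strategy: str = "degree-entropy"
) -> Partition:
    """Return the minimum-entropy partition.

    Ties break by fewer modules, then earlier grid order.  Raises if every
    partition is empty (a sign the detection parameters need review).
    """
    if not partitions:
        raise ValueError("no partitions to select from")
    if all(not p.modules for p in partitions):
        raise ValueError(
            "all partitions are empty; review detection parameters "
            "(degree cutoff / minimum module size) for this network"
        )
    score_partitions(partitions, strategy)
    indexed = [
        (p.entropy, len(p.modules), p.grid_index if p.grid_index is not None else i, p)
        for i, p in enumerate(partitions)
        if p.modules
    ]
    return min(indexed, key=lambda t: t[:3])[3]
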