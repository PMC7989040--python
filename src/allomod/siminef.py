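"""Node/edge Jaccard similarity between modules (the SimiNEF measure).

For modules m_i, m_j with node sets N and retained edge sets E:

    S_n = |N_i and N_j| / |N_i or N_j|        node Jaccard
    S_e = |E_i and E_j| / |E_i or E_j|        edge Jaccard
    S_ne = min(S_n, S_e)

The combined level S_ne carries both-exceed semantics: S_ne > t holds exactly
when S_n > t and S_e > t simultaneously, for every threshold t; min is the
unique monotone scalar with that property.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .graph_io import Module

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SimilarityRecord:
    stage_a: str
    id_a: str
    stage_b: str
    id_b: str
    s_n: float
    s_e: float
    s_ne: float


def _jaccard(a: frozenset, b: frozenset) -> float:
    union = len(a | b)
    return len(a & b) / union if union else 0.0


def node_similarity(a: Module, b: Module) -> float:
    """Jaccard index of the two node sets; 1 iff identical, 0 iff disjoint."""
    if not a.nodes or not b.nodes:
        raise ValueError("node similarity requires nonempty modules")
    return _jaccard(a.nodes, b.nodes)


def edge_similarity(a: Module, b: Module) -> float:
    """Jaccard index of the two unordered edge sets.

    Both-empty edge sets cannot occur for modules surviving the 2-core rule,
    but are handled defensively as 0 with a warning.
    """
    if not a.edges and not b.edges:
        logger.warning(
            "edge similarity of edgeless modules %s/%s: undefined, returning 0",
            a.module_id, b.module_id,
        )
        return 0.0
    return _jaccard(a.edges, b.edges)


def combined_similarity(a: Module, b: Module) -> float:
    return min(node_similarity(a, b), edge_similarity(a, b))


def similarity_record(a: Module, b: Module) -> SimilarityRecord:
    s_n = node_similarity(a, b)
    s_e = edge_similarity(a, b)
    return SimilarityRecord(
        stage_a=a.stage_label, id_a=a.module_id,
        stage_b=b.stage_label, id_b=b.module_id,
        s_n=s_n, s_e=s_e, s_ne=min(s_n, s_e),
    )


def pairwise_similarity(
    set_a: list[Module], set_b: list[Module], include_zero: bool = False
) -> tuple[list[SimilarityRecord], int]:
    """All cross-stage module-pair similarities, deterministically ordered.

    Returns ``(records, n_zero_pairs)``; by default records cover only pairs
    with S_ne > 0 and the count of all-zero pairs is the sparse summary.
    """
    stages_a = {m.stage_label for m in set_a}
    stages_b = {m.stage_label for m in set_b}
    if stages_a & stages_b:
        raise ValueError(f"stage labels must differ between sets: {stages_a & stages_b}")
    records: list[SimilarityRecord] = []
    n_zero = 0
    for a in sorted(set_a, key=lambda m: m.module_id):
        for b in sorted(set_b, key=lambda m: m.module_id):
            rec = similarity_record(a, b)
            if rec.s_ne > 0 or include_zero:
                records.append(rec)
            if rec.s_ne == 0:
                n_zero += 1
    return records, n_zero
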