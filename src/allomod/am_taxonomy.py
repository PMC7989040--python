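"""Classification of modules across three ordered disease stages.

Comparing each module against the modules of the other stages by the combined
node/edge similarity S_ne yields four allosteric-module (AM) classes:

* **DEM** (disease-exclusive): no edge overlap with any module of the other
  stages — S_ne = 0 throughout, or node-only overlap (S_n > 0 but S_e = 0).
* **CAM** (conserved): identical node *and* edge sets between stages
  (S_ne = 100%) — pairwise or across all three stages.
* **TAM** (transitional): partial overlap (0 < S_ne < 100%) between the first
  two stages only, with neither member overlapping any terminal-stage module.
* **OAM** (oncogenic): partial overlap involving the terminal (cancer) stage —
  a stage 1-3 pair, a stage 2-3 pair, or a connected triple with all three
  pairwise similarities strictly between 0 and 1.

Stage roles are positional (ordered list), so the taxonomy applies to any
ordered disease progression, not only CHB -> cirrhosis -> HCC.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from itertools import combinations

from .graph_io import Module
from .siminef import SimilarityRecord, similarity_record

DEFAULT_LEVELS = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)


class AMType(str, Enum):
    CAM = "CAM"
    TAM = "TAM"
    OAM = "OAM"


class DEMReason(str, Enum):
    NO_OVERLAP = "no_overlap"
    NODE_ONLY_OVERLAP = "node_only_overlap"


@dataclass
class AMAssociation:
    """A pair or connected triple of modules from distinct stages."""

    members: tuple[Module, ...]
    stage_span: tuple[int, ...]  # positional stage indices, ascending
    am_type: AMType
    pairwise: list[SimilarityRecord] = field(default_factory=list)

    @property
    def member_keys(self) -> tuple[tuple[str, str], ...]:
        return tuple((m.stage_label, m.module_id) for m in self.members)


@dataclass
class DEMLabel:
    module: Module
    stage_index: int
    reason: DEMReason


def _sim_table(stage_lists: list[list[Module]]):
    """All cross-stage pairwise similarity records, keyed by stage-index pair."""
    table: dict[tuple[int, int], dict[tuple[str, str], SimilarityRecord]] = {}
    for i, j in combinations(range(len(stage_lists)), 2):
        table[(i, j)] = {
            (a.module_id, b.module_id): similarity_record(a, b)
            for a in stage_lists[i]
            for b in stage_lists[j]
        }
    return table


def classify(
    stage1: list[Module], stage2: list[Module], stage3: list[Module]
) -> tuple[list[AMAssociation], list[DEMLabel]]:
    """Assign every module a DEM label or membership in >= 1 association.

    Precedence per pair: CAM (S_ne = 1) over partial overlap.  A stage 1-2
    partial pair is a TAM only if neither member has S_ne > 0 with any
    terminal-stage module; triples with all three pairwise S_ne in (0,1) form
    triple OAMs; pairs subsumed by an emitted triple (CAM or OAM) are not
    duplicated.  A module may participate in several associations.
    """
    stage_lists = [stage1, stage2, stage3]
    per_stage_labels = [{m.stage_label for m in lst} for lst in stage_lists]
    if any(len(s) > 1 for s in per_stage_labels):
        raise ValueError(f"mixed stage labels within a stage list: {per_stage_labels}")
    nonempty = [next(iter(s)) for s in per_stage_labels if s]
    if len(set(nonempty)) != len(nonempty):
        raise ValueError(f"duplicate stage labels across stages: {nonempty}")

    sims = _sim_table(stage_lists)
    associations: list[AMAssociation] = []
    covered_pairs: set[tuple[int, int, str, str]] = set()

    def rec(i: int, j: int, a: Module, b: Module) -> SimilarityRecord:
        return sims[(i, j)][(a.module_id, b.module_id)]

    # --- triples first (they absorb their member pairs) -------------------
    for a in stage1:
        for b in stage2:
            r_ab = rec(0, 1, a, b)
            for c in stage3:
                r_ac = rec(0, 2, a, c)
                r_bc = rec(1, 2, b, c)
                vals = (r_ab.s_ne, r_ac.s_ne, r_bc.s_ne)
                if all(v == 1.0 for v in vals):
                    associations.append(
                        AMAssociation((a, b, c), (0, 1, 2), AMType.CAM,
                                      [r_ab, r_ac, r_bc])
                    )
                elif all(0.0 < v < 1.0 for v in vals):
                    associations.append(
                        AMAssociation((a, b, c), (0, 1, 2), AMType.OAM,
                                      [r_ab, r_ac, r_bc])
                    )
                else:
                    continue
                covered_pairs.update({
                    (0, 1, a.module_id, b.module_id),
                    (0, 2, a.module_id, c.module_id),
                    (1, 2, b.module_id, c.module_id),
                })

    # --- CAM pairs --------------------------------------------------------
    for (i, j), table in sorted(sims.items()):
        for (ida, idb), r in sorted(table.items()):
            if r.s_ne == 1.0 and (i, j, ida, idb) not in covered_pairs:
                a = next(m for m in stage_lists[i] if m.module_id == ida)
                b = next(m for m in stage_lists[j] if m.module_id == idb)
                associations.append(AMAssociation((a, b), (i, j), AMType.CAM, [r]))
                covered_pairs.add((i, j, ida, idb))

    # --- OAM pairs involving the terminal stage ---------------------------
    for (i, j) in ((0, 2), (1, 2)):
        for (ida, idb), r in sorted(sims[(i, j)].items()):
            if 0.0 < r.s_ne < 1.0 and (i, j, ida, idb) not in covered_pairs:
                a = next(m for m in stage_lists[i] if m.module_id == ida)
                b = next(m for m in stage_lists[j] if m.module_id == idb)
                associations.append(AMAssociation((a, b), (i, j), AMType.OAM, [r]))
                covered_pairs.add((i, j, ida, idb))

    # --- stage 1-2 partial pairs: TAM if the terminal-stage exclusion holds
    def overlaps_terminal(m: Module, stage_idx: int) -> bool:
        pair = (0, 2) if stage_idx == 0 else (1, 2)
        return any(
            r.s_ne > 0
            for (ida, _), r in sims[pair].items()
            if ida == m.module_id
        )

    for (ida, idb), r in sorted(sims[(0, 1)].items()):
        if not (0.0 < r.s_ne < 1.0) or (0, 1, ida, idb) in covered_pairs:
            continue
        a = next(m for m in stage_lists[0] if m.module_id == ida)
        b = next(m for m in stage_lists[1] if m.module_id == idb)
        if not overlaps_terminal(a, 0) and not overlaps_terminal(b, 1):
            am_type = AMType.TAM
        else:
            # residual: terminal-stage involvement is indirect, via a member's
            # own stage-3 overlap; keeps every module covered by an association
            am_type = AMType.OAM
        associations.append(AMAssociation((a, b), (0, 1), am_type, [r]))
        covered_pairs.add((0, 1, ida, idb))

    # --- DEMs: everything not in any association --------------------------
    in_assoc = {key for assoc in associations for key in assoc.member_keys}
    dems: list[DEMLabel] = []
    for idx, lst in enumerate(stage_lists):
        for m in lst:
            if (m.stage_label, m.module_id) in in_assoc:
                continue
            node_only = False
            for (i, j), table in sims.items():
                pos = 0 if i == idx else (1 if j == idx else None)
                if pos is None:
                    continue
                for (ida, idb), r in table.items():
                    mid = ida if pos == 0 else idb
                    if mid == m.module_id and r.s_n > 0:
                        node_only = True
            reason = DEMReason.NODE_ONLY_OVERLAP if node_only else DEMReason.NO_OVERLAP
            dems.append(DEMLabel(module=m, stage_index=idx, reason=reason))
    return associations, dems


def venn_counts(
    stage1: list[Module],
    stage2: list[Module],
    stage3: list[Module],
    levels: tuple[float, ...] = DEFAULT_LEVELS,
) -> dict[str, dict[float, dict[str, int]]]:
    """Overlap counts per Venn region across a sweep of S_ne levels.

    Levels must be ascending; every level t below the top counts overlaps with
    S_ne > t, while the top level counts exact equality (S_ne = 100%).  Region
    counts are cumulative (an overlap qualifying for the triple region still
    counts in its pairwise regions), which makes every pairwise and triple
    count non-increasing in the level.  Both the number of qualifying
    associations and the number of distinct participating modules are
    reported; ``only<i>`` regions count stage-i modules with no qualifying
    overlap at that level.
    """
    if list(levels) != sorted(levels):
        raise ValueError("levels must be sorted ascending")
    stage_lists = [stage1, stage2, stage3]
    sims = _sim_table(stage_lists)
    top = levels[-1]
    region_names = {(0, 1): "1∩2", (1, 2): "2∩3", (0, 2): "1∩3"}
    out: dict[str, dict[float, dict[str, int]]] = {
        name: {} for name in list(region_names.values()) + ["1∩2∩3", "only1", "only2", "only3"]
    }

    for level in levels:
        def q(s: float) -> bool:
            return s == top if level == top else s > level

        qualifying: dict[tuple[int, int], set[tuple[str, str]]] = {}
        for (i, j), table in sims.items():
            qualifying[(i, j)] = {pair for pair, r in table.items() if q(r.s_ne)}

        for (i, j), name in region_names.items():
            pairs = qualifying[(i, j)]
            mods = {(i, a) for a, _ in pairs} | {(j, b) for _, b in pairs}
            out[name][level] = {"associations": len(pairs), "modules": len(mods)}

        triples = [
            (a.module_id, b.module_id, c.module_id)
            for a in stage1 for b in stage2 for c in stage3
            if (a.module_id, b.module_id) in qualifying[(0, 1)]
            and (a.module_id, c.module_id) in qualifying[(0, 2)]
            and (b.module_id, c.module_id) in qualifying[(1, 2)]
        ]
        tmods = {(0, t[0]) for t in triples} | {(1, t[1]) for t in triples} | {(2, t[2]) for t in triples}
        out["1∩2∩3"][level] = {"associations": len(triples), "modules": len(tmods)}

        for idx in range(3):
            overlapping: set[str] = set()
            for (i, j), pairs in qualifying.items():
                for a, b in pairs:
                    if i == idx:
                        overlapping.add(a)
                    if j == idx:
                        overlapping.add(b)
            n_excl = sum(1 for m in stage_lists[idx] if m.module_id not in overlapping)
            out[f"only{idx + 1}"][level] = {"associations": n_excl, "modules": n_excl}
    return out
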