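"""Hypergeometric gene-set over-representation for module gene lists.

With a background universe of N genes, a term annotating K of them, and a
module of n background genes of which k carry the term, the enrichment
p-value is the upper hypergeometric tail P(X >= k).  Benjamini-Hochberg
q-values are attached within each module's family of term tests; raw p-values
are always reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    module_id: str
    k: int  # term genes in module
    K: int  # term genes in background
    n: int  # module genes in background
    N: int  # background size
    p_value: float
    q_value: float
    overlap_genes: frozenset[str]


def hypergeom_enrich(
    module_genes: Iterable[str],
    annotation: Mapping[str, frozenset[str] | set[str]],
    background: Iterable[str] | None = None,
    module_id: str = "",
) -> list[EnrichmentResult]:
    """One upper-tail hypergeometric test per term with K >= 1.

    The background defaults to the union of all annotation genes; module and
    term gene sets are intersected with it.  Results are sorted by ascending
    p-value (ties by term) with BH q-values attached.
    """
    ann = {t: set(g) for t, g in annotation.items()}
    if background is None:
        bg: set[str] = set().union(*ann.values()) if ann else set()
    else:
        bg = set(background)
    if not bg:
        raise ValueError("empty background gene universe")
    module = set(module_genes) & bg
    N, n = len(bg), len(module)

    rows: list[EnrichmentResult] = []
    for term in sorted(ann):
        term_genes = ann[term] & bg
        K = len(term_genes)
        if K < 1:
            continue
        overlap = module & term_genes
        k = len(overlap)
        # P(X >= k) == survival function at k-1
        p = float(hypergeom.sf(k - 1, N, K, n))
        p = min(max(p, 0.0), 1.0)
        rows.append(EnrichmentResult(term, module_id, k, K, n, N, p, 1.0, frozenset(overlap)))

    if rows:
        _, q, _, _ = multipletests([r.p_value for r in rows], method="fdr_bh")
        rows = [
            EnrichmentResult(r.term, r.module_id, r.k, r.K, r.n, r.N, r.p_value,
                             float(qi), r.overlap_genes)
            for r, qi in zip(rows, q)
        ]
    rows.sort(key=lambda r: (r.p_value, r.term))
    return rows


def pathway_overlap_counts(
    terms1: Iterable[str], terms2: Iterable[str], terms3: Iterable[str]
) -> dict[str, int | list[str]]:
    """Pairwise/triple intersections of significant term sets across stages,
    plus the remaining non-overlapping ("altered") terms per stage."""
    s1, s2, s3 = set(terms1), set(terms2), set(terms3)
    triple = s1 & s2 & s3
    overlapping = (s1 & s2) | (s1 & s3) | (s2 & s3)
    return {
        "pair_1_2": len(s1 & s2),
        "pair_2_3": len(s2 & s3),
        "pair_1_3": len(s1 & s3),
        "triple": len(triple),
        "altered_1": sorted(s1 - overlapping),
        "altered_2": sorted(s2 - overlapping),
        "altered_3": sorted(s3 - overlapping),
    }


def significant_terms(
    results: Iterable[EnrichmentResult], q_max: float = 0.05, use_q: bool = True
) -> set[str]:
    """Terms passing the significance cut (BH q < q_max by default;
    ``use_q=False`` thresholds the raw p-value instead)."""
    return {
        r.term for r in results if (r.q_value if use_q else r.p_value) < q_max
    }
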