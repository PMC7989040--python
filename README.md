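# allomod

Tools for tracking **allosteric modules** — functional network modules whose
architecture changes — across an ordered disease progression, with a
random-forest pipeline for evaluating small biomarker gene panels.

The motivating setting is hepatitis-B-driven liver disease, where patients
progress through chronic hepatitis B (CHB) → cirrhosis → hepatocellular
carcinoma (HCC). Each stage has its own disease-associated gene network;
comparing the dense modules of those networks reveals which molecular
machines are conserved, which disappear before cancer, and which transform
on the way into it. The same machinery applies to any three ordered
condition-specific networks.

## What it computes

**Module detection.** Each stage network is clustered with a
re-implementation of the MCODE algorithm (core-clustering-coefficient vertex
weights, seeded greedy expansion, 2-core filter, optional haircut/fluff
post-processing). All 48 combinations of the detection parameters
(node score cutoff ∈ {0, 0.2, 0.3} × haircut ∈ {T,F} × fluff ∈ {T,F} ×
max depth ∈ {100, 5, 4, 3}, with degree cutoff 3 and k-core 2 fixed) are
swept, and the partition minimizing a network-entropy criterion is kept.

**Module similarity.** For modules *m<sub>i</sub>*, *m<sub>j</sub>* with node
sets *N* and edge sets *E*:

    S_n = |N(m_i) ∩ N(m_j)| / |N(m_i) ∪ N(m_j)|
    S_e = |E(m_i) ∩ E(m_j)| / |E(m_i) ∪ E(m_j)|
    S_ne = min(S_n, S_e)

so that *S<sub>ne</sub>* > *t* means both node and edge overlap exceed *t*.

**Taxonomy.** Across stages 1 → 2 → 3, every module becomes one of:
*DEM* (disease-exclusive: no edge overlap with other stages), *CAM*
(conserved: *S<sub>ne</sub>* = 100%), *TAM* (transitional: partial overlap
confined to stages 1–2), or *OAM* (oncogenic: partial overlap involving the
terminal stage). OAM overlaps are further labelled by bridge shape
(one-edge / triangular / multiedge / fully contained) and by how much of
each module lies outside the overlap (node–node / node–module /
module–module changes). Modules are also tested for gene-set enrichment
with an exact hypergeometric upper tail and BH correction.

**Panel evaluation.** Given class-labeled expression data: Welch-t +
fold-change differential-expression filter; Pearson correlation screen
(r > 0.8, p < 0.001); per-module random-forest out-of-bag (OOB) screening;
mean-decrease-in-Gini importance ranking with backward elimination; an
exhaustive search over all 1/2/3-gene combinations of a candidate set
(41 forest runs for 6 candidates) ranked by AUC, G-mean and F-value; and
extraction of interpretable threshold rules from the fitted ensemble.

A seeded synthetic generator plants each module class (and expression data
with chosen correlations and effect sizes) so the whole pipeline is testable
end to end without external data.

## Worked example

```python
from allomod import (StageNetConfig, gen_stage_networks, planted_modules,
                     run_grid, select_min_entropy, classify)

cfg = StageNetConfig(seed=3)          # default: 1 CAM, 1 TAM, 1 OAM, 2 DEMs
networks, truth = gen_stage_networks(cfg)

# detect modules in the first stage over the full 48-point sweep
partitions = run_grid(networks[0], min_module_size=4)
best = select_min_entropy(partitions)
print(len(partitions), len(best.modules), f"{best.entropy:.3f}")

# classify the planted modules across the three stages
assocs, dems = classify(*planted_modules(networks, truth))
for a in assocs:
    print(a.am_type.value, [m.module_id for m in a.members],
          [round(r.s_ne, 3) for r in a.pairwise])
print("DEMs:", [d.module.module_id for d in dems])
```

prints

```
48 3 1.000
CAM ['CHB1', 'CIRRHOSIS1'] [1.0]
OAM ['CIRRHOSIS3', 'HCC1'] [0.034]
TAM ['CHB2', 'CIRRHOSIS2'] [0.176]
DEMs: ['CHB3', 'HCC2']
```

— 48 parameter combinations were swept; the chosen partition holds the three
planted CHB cliques at entropy 1.0 (cliques have uniform internal degree);
the conserved pair is recovered at *S<sub>ne</sub>* = 1, the transitional
pair at 0.176 (its node Jaccard is 0.43 but only 3 of 17 edges are shared),
the oncogenic pair shares exactly one edge (*S<sub>ne</sub>* = 0.034), and
the two stage-exclusive cliques come back as DEMs.

The same steps are available from the shell:

```
allomod simulate networks --seed 3 --outdir fixtures/
allomod detect --network fixtures/chb.sif --stage CHB --out parts.json
allomod select --partitions parts.json --out chb_modules.json
allomod classify --modules chb.json,cirr.json,hcc.json --out am.json
```

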