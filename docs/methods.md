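# Methods

## Stage networks and modules

A stage network is an undirected simple graph over gene symbols
(case-normalized to upper case, since public annotations mix `cyp1a2` and
`CYP1A2`). Self-loops and duplicate records are dropped at load time; the
SIF interaction-type column is ignored because the networks are typeless
gene graphs. Directionality is never used: module detection and all
similarity measures operate on undirected topology. A module is a named
node set together with the induced edges retained at detection time; modules
with fewer than 4 nodes are dropped from reporting, applied *before* entropy
selection (the selection then compares like with like across grid points).

## MCODE detection

The detector follows the classic three-phase molecular-complex-detection
scheme. Vertex weight = (highest k-core number *k* of the node's closed
neighborhood) × (edge density of that k-core), with weight 0 for nodes of
degree < 3 (the fixed degree cutoff). Density excludes loops,
|E| / (n(n−1)/2), consistent with loops being disabled throughout. Seeds are
taken in descending weight, ties broken by lexicographically smallest gene
symbol for reproducibility. Expansion is breadth-first, admitting an
unvisited neighbor iff its weight ≥ seed weight × (1 − node score cutoff),
up to the max-depth hop limit; admitted nodes are marked visited, so
pre-fluff complexes are node-disjoint. Complexes without a 2-core are
discarded. Haircut iteratively removes nodes of within-complex degree < 2 to
a fixed point (a single pass can strand new degree-1 nodes). Fluff runs
after haircut and appends never-admitted boundary neighbors whose
closed-neighborhood density exceeds the fluff cutoff (default 0.1, the
reference tool's default, exposed as a parameter); fluffed nodes are not
marked visited and may appear in several modules, which downstream
similarity treats as plain node/edge sets.

The sweep enumerates node score cutoff {0.0, 0.2, 0.3} × haircut {T, F} ×
fluff {T, F} × max depth {100, 5, 4, 3} = 48 combinations, in that fixed
nesting order.

## Entropy selection

The criterion the detection sweep optimizes is made explicit and
configurable, because "minimum network entropy" admits several readings.
The default scores a module by the Shannon entropy of its internal-degree
distribution, normalized by log₂ n so every clique scores exactly 1; the
partition score is the module-size-weighted mean, minimized over the 48
partitions. Under this default a hub-dominated module (e.g. a 4-star,
0.8962) scores *below* a clique — the criterion prefers sharply
hub-structured modules; this consequence is asserted in the tests as
written. Two alternatives are selectable: the unnormalized degree entropy
and the entropy of the module-size distribution −Σ (n_m/N) log₂(n_m/N).
All strategies are invariant under gene relabeling. Ties break toward fewer
modules, then earlier grid order; empty partitions are never selected, and
an all-empty sweep raises an error advising parameter review.

## Similarity and taxonomy

S_n and S_e are plain Jaccard indices of node and edge sets; S_ne is their
minimum — the unique monotone scalar for which S_ne > t coincides with
"both S_n > t and S_e > t" at every threshold. Two modules with shared
nodes but no shared edge (S_n > 0, S_e = 0) count as non-overlapping, the
node-only disease-exclusive case.

Classification over three ordered stages, per module pair: S_ne = 1 ⇒
conserved (CAM; three identical modules collapse into one triple rather
than three pairs); partial overlap involving the terminal stage ⇒ oncogenic
(OAM), with all-partial connected triples emitted as one triple OAM whose
member pairs are not double-reported; partial overlap between stages 1–2 ⇒
transitional (TAM) only when *neither* member has S_ne > 0 with any
terminal-stage module. A 1–2 partial pair that fails that exclusion but
forms no valid triple is emitted as an OAM (terminal-stage involvement is
indirect, through a member's own stage-3 overlap); this keeps the
classification total — every module is a DEM or belongs to at least one
association, and never both. Associations are edges/triples over modules,
not a partition: one module may join several associations.

The Venn threshold sweep counts qualifying overlaps at S_ne > 0, > 20%, …,
> 80% and = 100% (the top level is exact equality). Counts are cumulative
per region — an overlap qualifying for the triple region still counts in
its pairwise regions — because exclusive Venn regions would not be monotone
in the level (a module can drop from the triple region into a pairwise
region as the threshold rises). Both the number of qualifying associations
and the number of distinct participating modules are reported.

## Topology of oncogenic overlaps

Overlap structures are checked in precedence order fully-contained (node
and edge subset) → triangular (exactly 3 shared nodes and 3 edges) →
multiedge (> 3 shared nodes, ≥ 3 shared edges) → one-edge (exactly 1 shared
edge). Shapes matching no literal category (e.g. a 3-node shared path) fall
back to multiedge so the labelling is exhaustive; `strict=True` raises
instead. Change types threshold the per-side counts of member-exclusive
*nodes* at 3 (edge deltas do not enter): both < 3 node–node, exactly one
≥ 3 node–module, both ≥ 3 module–module.

## Enrichment

Over-representation uses the exact hypergeometric upper tail
P(X ≥ k) with the background defaulting to the union of annotation genes.
Benjamini–Hochberg q-values are attached within each module's family of
term tests; raw p-values are always emitted too, and the significance cut
for cross-stage pathway-overlap counting defaults to q < 0.05 and is
configurable.

## Panel evaluation

The differential-expression filter is a conjunction: Welch two-sided t-test
p < 0.05 AND signed fold change beyond ±1.5, where the fold change is the
ratio of group means with the negative-reciprocal convention for
down-regulation. Welch rather than pooled-variance t is used because group
sizes and variances are generally unequal. Correlation screening pools all
samples regardless of class (per-class correlation is a separate call),
with p-values from the t-transform of r at n − 2 degrees of freedom, and no
multiplicity correction by default (BH is available).

The forest learner is injectable; the default is scikit-learn's
`RandomForestClassifier` with that library's default hyperparameters
(100 trees), `oob_score=True`, and a mandatory seed. 100 trees also matches
the rule-extraction window exactly. Per-class OOB error comes from the OOB
decision function; a sample never out of bag (vanishingly rare at 100
trees) falls back to the majority class. Module screening keeps a module
when its minimum per-class OOB error beats 0.5 by default; the screened
class is configurable. Backward elimination drops the lowest-MDG gene per
step and picks the gene set minimizing total OOB error, ties to the smaller
set. The combination search evaluates every subset of each requested size
(41 forests for 6 candidates at sizes 1–3) and ranks by AUC, then G-mean,
then F-value; metrics are OOB-based, so no held-out split is required
(a stratified 4:1 split helper exists for users who want one). AUC is the
Mann–Whitney rank statistic over scores.

Rule extraction walks every root-to-leaf path of the first 100 trees,
truncates paths to 6 conditions, merges duplicate (gene, comparator)
conditions to the most binding threshold, and prunes each rule by
sequentially deleting any single condition whose removal does not increase
training error. Rule selection is greedy by (error ascending, frequency
descending); the complexity-guided regularized selection used in some rule
frameworks is deliberately not reproduced — the greedy ranking is a
documented simplification.

## Synthetic generator

Planted structures are cliques (size ≥ 4 so they pass the degree-3
weighting and the size filter), one namespace per directive, disjoint
within a stage; overlaps exist only where a directive requires them.
Transitional-pair node-Jaccard targets are hit constructively (shared-node
count m with m/(2s − m) closest to target, required within ±0.05, else an
error lists feasible targets) rather than by rejection sampling, for
determinism. Oncogenic bridge shapes come from cliques sharing 2 / 3 / 4
nodes (one-edge / triangular / multiedge) or from nested cliques (fully
contained). The background is an Erdős–Rényi draw thinned to a spanning
forest by default: a background cycle of length ≥ 4 is itself a 2-core that
detection would report, so acyclicity is what guarantees the planted truth
table is exhaustive; `acyclic_background=False` gives the raw G(n, p).

Expression data are multivariate normal per class around a baseline
intensity of 10 with unit noise SD: planted pairs impose Pearson
correlations (identical in both classes; a non-PSD request errors with a
nearest-PSD hint), planted effects shift the positive-class mean in units
of the noise SD. Gaussian marginals (log-normal optional) are a deliberate
idealization — the pipeline is distribution-agnostic and its consumers
(t-tests, correlations, forests) do not assume counts. What passing tests
show is therefore recovery under well-specified signal and independence
assumptions; real microarray/RNA-seq data add heteroskedasticity, batch
structure and heavy tails that the generator does not emulate.

## Problem sizes and determinism

Closed-loop checks run at desk scale by design: taxonomy recovery over 20
seeded syntheses of ~70-node stage networks; panel recovery with 2σ
three-gene signals at n = 100 + 100 samples and 20 genes, 50 seeds in the
test suite and 20 in the acceptance script; null calibration on 1000 genes
at n = 20 + 20. Every stochastic step takes an explicit seed and identical
seeds give identical outputs, including module ordering (all tie-breaks are
lexicographic).

## Known limitations

Module counts and taxonomy tallies on real disease networks depend on the
input networks themselves; the package reproduces procedures and their
printed cardinalities/identities, not dataset-specific counts. The entropy
criterion's original formulation is not public, so the default here is a
declared choice, not a reconstruction. Fluff semantics differ subtly among
MCODE implementations (ordering relative to haircut, visited-marking); the
choices above are fixed and tested but may not bit-match other tools.
Class imbalance is reported (per-class OOB) but not corrected.
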