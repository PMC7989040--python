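"""Biomarker gene-panel evaluation with random forests.

The pipeline mirrors a standard candidate-panel workflow on class-labeled
expression data:

1. differential-expression filter (Welch t-test p < 0.05 and fold change
   beyond +/-1.5, signed-ratio convention);
2. correlation screen for highly coupled gene pairs (Pearson r > 0.8,
   p < 0.001 from the t-transform of r);
3. per-module random-forest screening by out-of-bag (OOB) error;
4. importance ranking by mean decrease in Gini (MDG) and backward
   elimination of the least important gene;
5. exhaustive search over all 1/2/3-gene combinations of a small candidate
   set (41 forest runs for 6 candidates), ranked by AUC / G-mean / F-value;
6. extraction of interpretable decision rules from the fitted ensemble.

The forest learner is injectable; the default is scikit-learn's
``RandomForestClassifier`` with that library's default hyperparameters and a
mandatory seed.  All OOB quantities come from the bagged ensemble itself, so
no held-out split is required (a stratified 4:1 split helper is provided for
users who want one).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import train_test_split

from .graph_io import Module

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# metrics
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ClassificationMetrics:
    auc: float
    g_mean: float
    f_value: float
    sensitivity: float
    specificity: float
    precision: float
    accuracy: float
    oob_error_total: float | None = None
    oob_error_per_class: dict | None = None


def compute_metrics(
    y_true: Sequence, y_pred: Sequence, scores: Sequence[float], positive_class,
    oob_error_total: float | None = None, oob_error_per_class: dict | None = None,
) -> ClassificationMetrics:
    """Binary classification metric suite.

    Sensitivity/precision/F-value quantify performance on the positive
    (tumor) class, specificity on the negative class, the G-mean balances
    both, and AUC is the rank statistic (Mann-Whitney) over ``scores``
    (higher score = more positive).
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    scores = np.asarray(scores, dtype=float)
    classes = set(y_true.tolist())
    if len(classes) < 2:
        raise ValueError("AUC undefined: ground truth contains a single class")
    pos = y_true == positive_class
    tp = int(np.sum(pos & (y_pred == positive_class)))
    fn = int(np.sum(pos & (y_pred != positive_class)))
    tn = int(np.sum(~pos & (y_pred != positive_class)))
    fp = int(np.sum(~pos & (y_pred == positive_class)))
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    prec = tp / (tp + fp) if tp + fp else 0.0
    acc = (tp + tn) / len(y_true)
    g_mean = math.sqrt(sens * spec)
    f_value = 2 * prec * sens / (prec + sens) if prec + sens else 0.0
    auc = float(roc_auc_score(pos.astype(int), scores))
    return ClassificationMetrics(
        auc=auc, g_mean=g_mean, f_value=f_value, sensitivity=sens,
        specificity=spec, precision=prec, accuracy=acc,
        oob_error_total=oob_error_total, oob_error_per_class=oob_error_per_class,
    )


# --------------------------------------------------------------------------
# differential expression and correlation screens
# --------------------------------------------------------------------------

def de_filter(
    expr: pd.DataFrame,
    labels: pd.Series,
    class_a,
    class_b,
    p_max: float = 0.05,
    fc_min: float = 1.5,
) -> list[str]:
    """Genes differentially expressed between two classes.

    A gene passes when the Welch t-test p-value is below ``p_max`` AND the
    signed fold change (ratio of group means; negative reciprocal when class b
    exceeds class a) lies beyond +/- ``fc_min``.
    """
    ia = labels == class_a
    ib = labels == class_b
    if ia.sum() < 2 or ib.sum() < 2:
        raise ValueError("both classes need >= 2 samples")
    a = expr.loc[ia.values if len(ia) == len(expr) else ia]
    b = expr.loc[ib.values if len(ib) == len(expr) else ib]
    out: list[str] = []
    for gene in expr.columns:
        xa, xb = a[gene].to_numpy(float), b[gene].to_numpy(float)
        if xa.std(ddof=1) == 0 and xb.std(ddof=1) == 0:
            logger.warning("gene %s: zero variance in both groups, excluded", gene)
            continue
        ma, mb = xa.mean(), xb.mean()
        if ma <= 0 or mb <= 0:
            logger.warning("gene %s: nonpositive group mean, fold change undefined; excluded", gene)
            continue
        fc = ma / mb
        if fc < 1.0:
            fc = -mb / ma
        if not (fc > fc_min or fc < -fc_min):
            continue
        _, p = stats.ttest_ind(xa, xb, equal_var=False)
        if p < p_max:
            out.append(gene)
    return out


@dataclass(frozen=True)
class CorrelationRecord:
    gene_a: str
    gene_b: str
    r: float
    p_value: float


def correlated_pairs(
    expr: pd.DataFrame,
    genes: Iterable[str] | None = None,
    r_min: float = 0.8,
    p_max: float = 0.001,
) -> list[CorrelationRecord]:
    """All unordered gene pairs with Pearson r > ``r_min`` and p < ``p_max``.

    The p-value comes from the t-transform of r with n-2 degrees of freedom;
    all samples are pooled regardless of class.  Constant genes are skipped
    with a warning.
    """
    cols = sorted(set(genes) & set(expr.columns)) if genes is not None else list(expr.columns)
    n = len(expr)
    if n < 3:
        raise ValueError("correlation screen needs >= 3 samples")
    x = expr[cols].to_numpy(float)
    sd = x.std(axis=0, ddof=1)
    keep = sd > 0
    dropped = [c for c, k in zip(cols, keep) if not k]
    if dropped:
        logger.warning("constant genes skipped in correlation screen: %s", dropped)
    cols = [c for c, k in zip(cols, keep) if k]
    x = x[:, keep]
    if len(cols) < 2:
        return []
    r = np.corrcoef(x, rowvar=False)
    out: list[CorrelationRecord] = []
    for i, j in combinations(range(len(cols)), 2):
        rij = float(np.clip(r[i, j], -1.0, 1.0))
        if rij <= r_min:
            continue
        if abs(rij) == 1.0:
            p = 0.0
        else:
            t = rij * math.sqrt((n - 2) / (1 - rij * rij))
            p = 2 * float(stats.t.sf(abs(t), n - 2))
        if p < p_max:
            out.append(CorrelationRecord(cols[i], cols[j], rij, p))
    out.sort(key=lambda rec: (-rec.r, rec.gene_a, rec.gene_b))
    return out


# --------------------------------------------------------------------------
# forests
# --------------------------------------------------------------------------

ForestFactory = Callable[[int], RandomForestClassifier]


def default_forest(seed: int) -> RandomForestClassifier:
    """Library-default random forest with OOB scoring and a fixed seed."""
    return RandomForestClassifier(oob_score=True, random_state=seed)


def _oob_predictions(forest: RandomForestClassifier):
    """OOB predicted labels and class-probability rows, NaN-safe.

    A sample never out of bag (vanishingly rare at >= 100 trees) falls back
    to the ensemble's in-bag prediction for that sample.
    """
    proba = forest.oob_decision_function_
    bad = np.isnan(proba).any(axis=1) | (np.nansum(proba, axis=1) == 0)
    pred_idx = np.zeros(len(proba), dtype=int)
    ok = ~bad
    pred_idx[ok] = np.argmax(proba[ok], axis=1)
    return proba, pred_idx, bad


def fit_forest(
    X: np.ndarray, y: Sequence, seed: int, factory: ForestFactory = default_forest
):
    forest = factory(seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # sklearn warns when few samples are OOB
        forest.fit(X, np.asarray(y))
    return forest


def oob_report(forest: RandomForestClassifier, y: Sequence):
    """Total and per-class OOB error plus OOB labels/scores."""
    y = np.asarray(y)
    classes = list(forest.classes_)
    proba, pred_idx, bad = _oob_predictions(forest)
    y_pred = np.asarray(classes)[pred_idx]
    if bad.any():
        # sample never out of bag: fall back to the majority training class
        vals, counts = np.unique(y, return_counts=True)
        y_pred = y_pred.copy()
        y_pred[bad] = vals[np.argmax(counts)]
    total = float(np.mean(y_pred != y))
    per_class = {
        c: float(np.mean(y_pred[y == c] != c)) for c in classes if np.any(y == c)
    }
    return total, per_class, y_pred, proba


def _positive_scores(forest, proba, positive_class) -> np.ndarray:
    idx = list(forest.classes_).index(positive_class)
    scores = proba[:, idx]
    return np.nan_to_num(scores, nan=0.5)


# --------------------------------------------------------------------------
# module screening, importance, elimination, combination search
# --------------------------------------------------------------------------

def module_oob_screen(
    expr: pd.DataFrame,
    labels: pd.Series,
    modules: Sequence[Module],
    seed: int,
    oob_max: float = 0.5,
    screened_class=None,
    factory: ForestFactory = default_forest,
) -> tuple[list[Module], dict[str, dict]]:
    """Keep modules whose forest separates some class with OOB error < ``oob_max``.

    One forest per module, fit on the module's genes present in the matrix.
    By default a module survives when its *minimum* per-class OOB error beats
    the cutoff; pass ``screened_class`` to screen one class specifically.
    Modules with no genes in the matrix are dropped with a warning.
    """
    y = labels.to_numpy()
    kept: list[Module] = []
    report: dict[str, dict] = {}
    for i, mod in enumerate(modules):
        genes = sorted(mod.nodes & set(expr.columns))
        if not genes:
            logger.warning("module %s: no genes in expression matrix, dropped", mod.module_id)
            continue
        forest = fit_forest(expr[genes].to_numpy(float), y, seed + i, factory)
        total, per_class, _, _ = oob_report(forest, y)
        if screened_class is not None:
            passes = per_class.get(screened_class, 1.0) < oob_max
        else:
            passes = min(per_class.values()) < oob_max
        report[mod.module_id] = {
            "genes": genes, "oob_error_total": total,
            "oob_error_per_class": per_class, "kept": passes,
        }
        if passes:
            kept.append(mod)
    return kept, report


@dataclass(frozen=True)
class ImportanceRecord:
    gene: str
    mdg: float


def importance_ranking(forest, gene_names: Sequence[str]) -> list[ImportanceRecord]:
    recs = [
        ImportanceRecord(g, float(v))
        for g, v in zip(gene_names, forest.feature_importances_)
    ]
    recs.sort(key=lambda r: (-r.mdg, r.gene))
    return recs


def top_importance(forest, gene_names: Sequence[str], k: int = 5) -> list[ImportanceRecord]:
    """Top-k genes by mean decrease in Gini (k > gene count returns all)."""
    return importance_ranking(forest, gene_names)[: max(k, 0)]


def backward_eliminate(
    expr: pd.DataFrame,
    genes: Sequence[str],
    labels: pd.Series,
    seed: int,
    factory: ForestFactory = default_forest,
):
    """Iteratively drop the least important (lowest-MDG) gene and refit.

    Returns ``(trajectory, best_genes)``; each trajectory step records the
    gene set, its total and per-class OOB error, and the MDG ranking.  The
    best set minimizes total OOB error, ties going to the smaller set (later
    step).
    """
    current = sorted(genes)
    if len(current) < 2:
        raise ValueError("backward elimination needs >= 2 genes")
    y = labels.to_numpy()
    trajectory: list[dict] = []
    step = 0
    while current:
        forest = fit_forest(expr[current].to_numpy(float), y, seed + step, factory)
        total, per_class, _, _ = oob_report(forest, y)
        ranking = importance_ranking(forest, current)
        trajectory.append({
            "genes": tuple(current),
            "oob_error_total": total,
            "oob_error_per_class": per_class,
            "ranking": ranking,
        })
        if len(current) == 1:
            break
        least = ranking[-1].gene
        current = [g for g in current if g != least]
        step += 1
    best = min(trajectory, key=lambda t: (t["oob_error_total"], len(t["genes"])))
    return trajectory, best["genes"]


def combo_search(
    expr: pd.DataFrame,
    candidates: Sequence[str],
    labels: pd.Series,
    positive_class,
    sizes: Sequence[int] = (1, 2, 3),
    seed: int = 0,
    factory: ForestFactory = default_forest,
) -> list[tuple[tuple[str, ...], ClassificationMetrics]]:
    """Fit one forest per gene combination of each requested size.

    For 6 candidates and sizes {1,2,3} this is 6 + 15 + 20 = 41 forest runs.
    Metrics are OOB-based; rows are ranked by (AUC desc, G-mean desc, F-value
    desc), ties by the combination itself.
    """
    candidates = sorted(set(candidates))
    if len(candidates) < max(sizes):
        raise ValueError("fewer candidates than the largest combination size")
    y = labels.to_numpy()
    rows = []
    run = 0
    for size in sorted(sizes):
        for combo in combinations(candidates, size):
            forest = fit_forest(expr[list(combo)].to_numpy(float), y, seed + run, factory)
            total, per_class, y_pred, proba = oob_report(forest, y)
            scores = _positive_scores(forest, proba, positive_class)
            m = compute_metrics(y, y_pred, scores, positive_class,
                                oob_error_total=total, oob_error_per_class=per_class)
            rows.append((combo, m))
            run += 1
    rows.sort(key=lambda t: (-t[1].auc, -t[1].g_mean, -t[1].f_value, t[0]))
    return rows


def stratified_split(
    expr: pd.DataFrame, labels: pd.Series, test_fraction: float = 0.2, seed: int = 0
):
    """Stratified train/test split at the conventional 4:1 ratio."""
    idx_train, idx_test = train_test_split(
        np.arange(len(expr)), test_size=test_fraction,
        stratify=labels.to_numpy(), random_state=seed,
    )
    return (expr.iloc[idx_train], labels.iloc[idx_train],
            expr.iloc[idx_test], labels.iloc[idx_test])


# --------------------------------------------------------------------------
# rule extraction
# --------------------------------------------------------------------------

Comparator = str  # "<=" or ">"


@dataclass(frozen=True)
class Condition:
    gene: str
    comparator: Comparator
    threshold: float

    def matches(self, x: np.ndarray) -> np.ndarray:
        return x <= self.threshold if self.comparator == "<=" else x > self.threshold


@dataclass(frozen=True)
class Rule:
    conditions: tuple[Condition, ...]
    predicted_class: object
    frequency: float
    error: float

    @property
    def length(self) -> int:
        return len(self.conditions)


def _merge_conditions(conds: list[Condition]) -> list[Condition]:
    """Keep the most binding threshold per (gene, comparator)."""
    merged: dict[tuple[str, str], float] = {}
    order: list[tuple[str, str]] = []
    for c in conds:
        key = (c.gene, c.comparator)
        if key not in merged:
            merged[key] = c.threshold
            order.append(key)
        elif c.comparator == "<=":
            merged[key] = min(merged[key], c.threshold)
        else:
            merged[key] = max(merged[key], c.threshold)
    return [Condition(g, cmp_, merged[(g, cmp_)]) for g, cmp_ in order]


def _rule_stats(conds: Sequence[Condition], predicted, expr: pd.DataFrame, y: np.ndarray):
    mask = np.ones(len(expr), dtype=bool)
    for c in conds:
        mask &= c.matches(expr[c.gene].to_numpy(float))
    n = int(mask.sum())
    if n == 0:
        return 0.0, 1.0
    err = float(np.mean(y[mask] != predicted))
    return n / len(expr), err


def extract_rules(
    forest: RandomForestClassifier,
    gene_names: Sequence[str],
    expr: pd.DataFrame,
    labels: pd.Series,
    n_trees: int = 100,
    max_len: int = 6,
) -> list[Rule]:
    """Interpretable condition rules from the first ``n_trees`` trees.

    Every root-to-leaf path, truncated to ``max_len`` conditions, becomes a
    candidate rule predicting the leaf's majority class.  Duplicate
    (gene, comparator) conditions on a path are merged to the most binding
    threshold.  Each rule is pruned by sequentially deleting any single
    condition whose removal does not increase the rule's training error
    (leave-one-out pruning of variable-value pairs).  Zero-coverage rules are
    dropped; duplicates collapse; output sorts by (error asc, frequency desc,
    length asc).
    """
    if not hasattr(forest, "estimators_"):
        raise ValueError("forest is not fitted")
    y = labels.to_numpy()
    classes = list(forest.classes_)
    raw: dict[tuple[tuple[Condition, ...], object], None] = {}

    for est in forest.estimators_[:n_trees]:
        tree = est.tree_
        stack: list[tuple[int, list[Condition]]] = [(0, [])]
        while stack:
            node, conds = stack.pop()
            if tree.children_left[node] == -1:  # leaf
                predicted = classes[int(np.argmax(tree.value[node][0]))]
                merged = tuple(_merge_conditions(conds[:max_len]))
                if merged:
                    raw[(merged, predicted)] = None
                continue
            gene = gene_names[tree.feature[node]]
            thr = float(tree.threshold[node])
            stack.append((tree.children_right[node], conds + [Condition(gene, ">", thr)]))
            stack.append((tree.children_left[node], conds + [Condition(gene, "<=", thr)]))

    pruned: dict[tuple[frozenset, object], Rule] = {}
    for (conds, predicted) in raw:
        conds = list(conds)
        freq, err = _rule_stats(conds, predicted, expr, y)
        if freq == 0.0:
            continue
        i = 0
        while len(conds) > 1 and i < len(conds):
            trial = conds[:i] + conds[i + 1:]
            t_freq, t_err = _rule_stats(trial, predicted, expr, y)
            if t_err <= err:
                conds, freq, err = trial, t_freq, t_err
            else:
                i += 1
        key = (frozenset(conds), predicted)
        rule = Rule(tuple(conds), predicted, freq, err)
        prev = pruned.get(key)
        if prev is None or (rule.error, -rule.frequency) < (prev.error, -prev.frequency):
            pruned[key] = rule
    out = sorted(
        pruned.values(),
        key=lambda r: (r.error, -r.frequency, r.length,
                       tuple((c.gene, c.comparator, c.threshold) for c in r.conditions)),
    )
    return out
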