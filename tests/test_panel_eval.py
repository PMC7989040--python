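"""Panel pipeline: metrics, screens, forests, combination search, rules."""

import math

import numpy as np
import pandas as pd
import pytest
from sklearn.ensemble import RandomForestClassifier

from allomod import (
    backward_eliminate,
    combo_search,
    compute_metrics,
    correlated_pairs,
    de_filter,
    extract_rules,
    fit_forest,
    gen_expression,
    module_oob_screen,
    oob_report,
    top_importance,
)
from allomod.synthetic import ExprConfig
from tests.conftest import clique_module

POS, NEG = "TUMOR", "NON_TUMOR"


def confusion_vectors(tp, fn, tn, fp):
    y_true = [POS] * (tp + fn) + [NEG] * (tn + fp)
    y_pred = [POS] * tp + [NEG] * fn + [NEG] * tn + [POS] * fp
    scores = [1.0] * tp + [0.0] * fn + [0.0] * tn + [1.0] * fp
    return y_true, y_pred, scores


class TestComputeMetrics:
    def test_published_identity_suite(self):
        # 84 tumor / 11 non-tumor test set with sens 80/84, spec 10/11
        m = compute_metrics(*confusion_vectors(tp=80, fn=4, tn=10, fp=1), POS)
        assert m.sensitivity == pytest.approx(0.9524, abs=5e-5)
        assert m.specificity == pytest.approx(0.9091, abs=5e-5)
        assert m.precision == pytest.approx(0.9877, abs=5e-5)
        assert m.g_mean == pytest.approx(0.9305, abs=5e-5)
        assert m.f_value == pytest.approx(0.9697, abs=5e-5)
        assert m.accuracy == pytest.approx(0.9474, abs=5e-5)

    def test_perfect_separation(self):
        m = compute_metrics(*confusion_vectors(tp=10, fn=0, tn=10, fp=0), POS)
        assert m.auc == 1.0 and m.g_mean == 1.0 and m.f_value == 1.0

    def test_identities_on_random_confusions(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            y_true = rng.choice([POS, NEG], size=60)
            if len(set(y_true)) < 2:
                continue
            y_pred = rng.choice([POS, NEG], size=60)
            scores = rng.random(60)
            m = compute_metrics(y_true, y_pred, scores, POS)
            assert m.g_mean == pytest.approx(
                math.sqrt(m.sensitivity * m.specificity), abs=1e-12)
            if m.precision + m.sensitivity > 0:
                assert m.f_value == pytest.approx(
                    2 * m.precision * m.sensitivity / (m.precision + m.sensitivity),
                    abs=1e-12)
            # AUC == brute-force pairwise concordance (ties count half)
            pos_s = scores[y_true == POS]
            neg_s = scores[y_true == NEG]
            conc = sum((p > n) + 0.5 * (p == n) for p in pos_s for n in neg_s)
            assert m.auc == pytest.approx(conc / (len(pos_s) * len(neg_s)), abs=1e-12)

    def test_single_class_truth_raises(self):
        with pytest.raises(ValueError, match="single class"):
            compute_metrics([POS, POS], [POS, NEG], [0.1, 0.9], POS)


class TestDEFilter:
    def _expr(self, a_vals, b_vals, gene="G1"):
        n_a, n_b = len(a_vals), len(b_vals)
        expr = pd.DataFrame({gene: list(a_vals) + list(b_vals)},
                            index=[f"S{i}" for i in range(n_a + n_b)])
        labels = pd.Series(["A"] * n_a + ["B"] * n_b, index=expr.index)
        return expr, labels

    def test_strong_effect_included(self):
        rng = np.random.default_rng(0)
        expr, labels = self._expr(rng.normal(300, 10, 10), rng.normal(100, 10, 10))
        assert de_filter(expr, labels, "A", "B") == ["G1"]

    def test_downregulation_signed_convention(self):
        rng = np.random.default_rng(1)
        expr, labels = self._expr(rng.normal(100, 10, 10), rng.normal(300, 10, 10))
        assert de_filter(expr, labels, "A", "B") == ["G1"]

    def test_small_fold_change_excluded_despite_tiny_p(self):
        rng = np.random.default_rng(2)
        expr, labels = self._expr(rng.normal(140, 1, 50), rng.normal(100, 1, 50))
        assert de_filter(expr, labels, "A", "B") == []

    def test_zero_variance_excluded(self):
        expr, labels = self._expr([5.0] * 5, [5.0] * 5)
        assert de_filter(expr, labels, "A", "B") == []

    def test_null_type_one_rate_without_fc_gate(self):
        # pure p<0.05 criterion on 1000 null genes: rate within 99% binomial CI
        cfg = ExprConfig(n_samples=(20, 20), n_genes=1000, seed=11)
        expr, labels = gen_expression(cfg)
        hits = de_filter(expr, labels, NEG, POS, fc_min=0.0)
        rate = len(hits) / 1000
        half = 2.576 * math.sqrt(0.05 * 0.95 / 1000)
        assert abs(rate - 0.05) < half


class TestCorrelatedPairs:
    def test_duplicated_column_r_one(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=36)
        expr = pd.DataFrame({"G1": x, "G2": x, "G3": rng.normal(size=36)})
        recs = correlated_pairs(expr)
        assert [(r.gene_a, r.gene_b) for r in recs] == [("G1", "G2")]
        assert recs[0].r == pytest.approx(1.0)

    def test_independent_columns_excluded(self):
        cfg = ExprConfig(n_samples=(18, 18), n_genes=10, seed=5)
        expr, _ = gen_expression(cfg)
        assert correlated_pairs(expr) == []

    def test_planted_rho_09_detected_in_most_replicates(self):
        hits = 0
        for seed in range(20):
            cfg = ExprConfig(n_samples=(18, 18), n_genes=5, seed=seed,
                             planted_pairs=(("G001", "G002", 0.9),))
            expr, _ = gen_expression(cfg)
            recs = correlated_pairs(expr)
            hits += any({r.gene_a, r.gene_b} == {"G001", "G002"} for r in recs)
        assert hits >= 18

    def test_constant_gene_skipped(self):
        expr = pd.DataFrame({"G1": np.ones(10), "G2": np.arange(10.0),
                             "G3": np.arange(10.0)})
        recs = correlated_pairs(expr)
        assert all("G1" not in (r.gene_a, r.gene_b) for r in recs)


def informative_expr(seed, n=(40, 40), informative=("G001", "G002", "G003"), shift=5.0,
                     n_genes=10):
    cfg = ExprConfig(n_samples=n, n_genes=n_genes, seed=seed,
                     planted_effects=tuple((g, shift) for g in informative))
    return gen_expression(cfg)


class TestModuleScreen:
    def test_separable_module_kept_noise_module_oob(self):
        expr, labels = informative_expr(0)
        informative = clique_module("info", "NET", ["G001", "G002", "G003", "G004"])
        noise = clique_module("noise", "NET", ["G007", "G008", "G009", "G010"])
        kept, report = module_oob_screen(expr, labels, [informative, noise], seed=1)
        assert informative in kept
        assert report["info"]["oob_error_total"] < 0.1

    def test_permuted_labels_module_dropped(self):
        expr, labels = informative_expr(1, n=(60, 60))
        rng = np.random.default_rng(9)
        shuffled = pd.Series(rng.permutation(labels.to_numpy()), index=labels.index)
        mod = clique_module("info", "NET", ["G001", "G002", "G003", "G004"])
        kept, report = module_oob_screen(expr, shuffled, [mod], seed=2, oob_max=0.4)
        assert kept == []

    def test_informative_beats_noise_in_paired_runs(self):
        wins = 0
        for seed in range(10):
            expr, labels = informative_expr(seed, shift=2.0)
            info = clique_module("info", "NET", ["G001", "G002", "G003", "G004"])
            noise = clique_module("noise", "NET", ["G007", "G008", "G009", "G010"])
            _, report = module_oob_screen(expr, labels, [info, noise], seed=seed)
            wins += (report["info"]["oob_error_total"]
                     < report["noise"]["oob_error_total"])
        assert wins >= 9

    def test_module_without_matching_genes_dropped(self):
        expr, labels = informative_expr(2)
        mod = clique_module("alien", "NET", ["ZZZ1", "ZZZ2", "ZZZ3", "ZZZ4"])
        kept, report = module_oob_screen(expr, labels, [mod], seed=0)
        assert kept == [] and "alien" not in report


class TestImportance:
    def test_informative_gene_ranks_first(self):
        wins = 0
        for seed in range(10):
            cfg = ExprConfig(n_samples=(40, 40), n_genes=10, seed=seed,
                             planted_effects=(("G001", 3.0),))
            expr, labels = gen_expression(cfg)
            forest = fit_forest(expr.to_numpy(), labels.to_numpy(), seed)
            ranking = top_importance(forest, list(expr.columns), k=5)
            wins += ranking[0].gene == "G001"
        assert wins >= 9

    def test_k_zero_and_k_too_large(self):
        expr, labels = informative_expr(3, n_genes=5)
        forest = fit_forest(expr.to_numpy(), labels.to_numpy(), 0)
        assert top_importance(forest, list(expr.columns), k=0) == []
        assert len(top_importance(forest, list(expr.columns), k=50)) == 5


class TestBackwardEliminate:
    def test_trajectory_bookkeeping(self):
        expr, labels = informative_expr(4, n_genes=6)
        traj, best = backward_eliminate(expr, list(expr.columns), labels, seed=0)
        assert len(traj) == 6
        sizes = [len(t["genes"]) for t in traj]
        assert sizes == list(range(6, 0, -1))
        assert set(best) <= set(expr.columns)

    def test_two_genes_trajectory_length_two(self):
        expr, labels = informative_expr(5, n_genes=4)
        traj, _ = backward_eliminate(expr, ["G001", "G002"], labels, seed=0)
        assert len(traj) == 2

    def test_informative_genes_survive(self):
        wins = 0
        for seed in range(5):
            expr, labels = informative_expr(seed, n=(30, 30), shift=3.0, n_genes=9)
            traj, best = backward_eliminate(expr, list(expr.columns), labels, seed=seed)
            wins += {"G001", "G002", "G003"} <= set(best) or len(set(best) & {"G001", "G002", "G003"}) >= 2
        assert wins >= 4

    def test_single_gene_rejected(self):
        expr, labels = informative_expr(6, n_genes=4)
        with pytest.raises(ValueError):
            backward_eliminate(expr, ["G001"], labels, seed=0)


class TestComboSearch:
    def test_41_combinations_for_six_candidates(self):
        expr, labels = informative_expr(7, n=(20, 20), n_genes=8)
        rows = combo_search(expr, [f"G{i:03d}" for i in range(1, 7)], labels, POS, seed=0)
        assert len(rows) == 41
        by_size = {s: sum(len(c) == s for c, _ in rows) for s in (1, 2, 3)}
        assert by_size == {1: 6, 2: 15, 3: 20}

    def test_single_size_counts(self):
        expr, labels = informative_expr(8, n=(20, 20), n_genes=5)
        rows = combo_search(expr, ["G001", "G002", "G003"], labels, POS, sizes=(1,), seed=0)
        assert len(rows) == 3

    def test_seed_determinism(self):
        expr, labels = informative_expr(9, n=(20, 20), n_genes=5)
        a = combo_search(expr, ["G001", "G002", "G003"], labels, POS, sizes=(1, 2), seed=5)
        b = combo_search(expr, ["G001", "G002", "G003"], labels, POS, sizes=(1, 2), seed=5)
        assert a == b


class TestRules:
    def _stump_forest(self, x, y):
        forest = RandomForestClassifier(n_estimators=1, max_depth=1,
                                        bootstrap=False, random_state=0)
        forest.fit(x, y)
        return forest

    def test_stump_yields_two_length_one_rules(self):
        x = np.linspace(0, 1, 20).reshape(-1, 1)
        y = np.array([NEG] * 10 + [POS] * 10)
        expr = pd.DataFrame(x, columns=["G1"])
        forest = self._stump_forest(x, y)
        rules = extract_rules(forest, ["G1"], expr, pd.Series(y))
        assert len(rules) == 2
        assert all(r.length == 1 for r in rules)

    def test_planted_threshold_rule_recovered(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 10, size=(200, 1))
        y = np.where(x[:, 0] > 6.0, POS, NEG)
        expr = pd.DataFrame(x, columns=["G1"])
        forest = fit_forest(x, y, seed=1)
        rules = extract_rules(forest, ["G1"], expr, pd.Series(y))
        tumor_rules = [r for r in rules if r.predicted_class == POS and r.error == 0.0]
        assert tumor_rules
        best = max(tumor_rules, key=lambda r: r.frequency)
        assert best.frequency == pytest.approx(np.mean(y == POS), abs=0.02)
        assert all(c.comparator == ">" for c in best.conditions)

    def test_rule_contract_and_pruning(self):
        expr, labels = informative_expr(10, n=(30, 30), n_genes=4)
        forest = fit_forest(expr.to_numpy(), labels.to_numpy(), 2)
        rules = extract_rules(forest, list(expr.columns), expr, labels, max_len=3)
        assert rules
        for r in rules:
            assert 1 <= r.length <= 3
            assert 0 < r.frequency <= 1
            assert 0 <= r.error <= 1
        errors = [r.error for r in rules]
        assert errors == sorted(errors)

    def test_unfit_forest_rejected(self):
        with pytest.raises(ValueError, match="not fitted"):
            extract_rules(RandomForestClassifier(), ["G1"],
                          pd.DataFrame({"G1": [1.0]}), pd.Series([POS]))


def test_oob_report_shapes():
    expr, labels = informative_expr(11, n=(25, 25), n_genes=5)
    forest = fit_forest(expr.to_numpy(), labels.to_numpy(), 3)
    total, per_class, y_pred, proba = oob_report(forest, labels.to_numpy())
    assert 0 <= total <= 1
    assert set(per_class) == {POS, NEG}
    assert len(y_pred) == len(labels) and proba.shape == (len(labels), 2)
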