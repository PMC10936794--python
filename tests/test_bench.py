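"""Confusion metrics, CV plans, ROC, the rule network, and the harness."""

import math

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from ventilab.bench import (
    ConfusionMatrix,
    CVPlan,
    RuleNetwork,
    confusion,
    evaluate_rule_network,
    kfold,
    metrics,
    roc,
    run_benchmark,
)
from ventilab.dataset import DatasetConfig, generate
from ventilab.errors import (
    ConfigurationError,
    DegenerateROCError,
    DomainError,
    ParameterError,
    PlanError,
    SignalError,
)


class TestConfusion:
    def test_perfect_positive_batch(self):
        cm = confusion([1] * 10, [1] * 10)
        assert (cm.tp, cm.tn, cm.fp, cm.fn) == (10, 0, 0, 0)

    def test_reported_pav_counts_total(self):
        assert ConfusionMatrix(121, 12, 2, 10).total == 145

    def test_swapping_positive_class_convention(self):
        cm = ConfusionMatrix(tp=5, tn=3, fp=2, fn=1)
        swapped = cm.swapped()
        assert (swapped.tp, swapped.tn, swapped.fp, swapped.fn) == (3, 5, 1, 2)
        # equivalently: recount with flipped labels
        y_true = [1] * 6 + [0] * 5
        y_pred = [1] * 5 + [0] + [1] * 2 + [0] * 3
        direct = confusion(y_true, y_pred)
        flipped = confusion(1 - np.array(y_true), 1 - np.array(y_pred))
        assert flipped == direct.swapped()

    def test_malformed_inputs_rejected(self):
        with pytest.raises(SignalError):
            confusion([0, 1], [1])
        with pytest.raises(SignalError):
            confusion([0, 2], [0, 1])
        with pytest.raises(ParameterError):
            ConfusionMatrix(-1, 0, 0, 1)


class TestMetrics:
    @pytest.mark.parametrize(
        "counts,accuracy_pct,precision,specificity,f1",
        [
            ((121, 12, 2, 10), 91.7, 0.9837, 0.8571, 0.953),
            ((118, 12, 5, 10), 89.7, 0.9593, 0.7059, 0.940),
            ((121, 11, 2, 11), 91.0, 0.9837, 0.8462, 0.949),
        ],
    )
    def test_reported_pressure_mode_worked_examples(
        self, counts, accuracy_pct, precision, specificity, f1
    ):
        """Published PAV pressure confusion counts reproduce the printed metrics."""
        report = metrics(ConfusionMatrix(*counts))
        assert report.accuracy_pct == accuracy_pct
        assert round(report.precision, 4) == precision
        assert round(report.specificity, 4) == specificity
        assert round(report.f1, 3) == f1

    def test_balanced_matrix(self):
        report = metrics(ConfusionMatrix(25, 25, 25, 25))
        assert report.accuracy == 0.5

    def test_f1_fixed_point_when_precision_equals_recall(self):
        # tp/(tp+fp) == tp/(tp+fn) == 0.8
        report = metrics(ConfusionMatrix(tp=8, tn=5, fp=2, fn=2))
        assert report.precision == report.sensitivity == pytest.approx(0.8)
        assert report.f1 == pytest.approx(0.8)

    def test_zero_denominators_flagged_not_raised(self):
        report = metrics(ConfusionMatrix(tp=0, tn=5, fp=0, fn=0))
        assert math.isnan(report.precision) and "precision" in report.undefined
        assert math.isnan(report.sensitivity) and "sensitivity" in report.undefined
        assert report.specificity == 1.0

    def test_f1_zero_when_no_true_positives(self):
        report = metrics(ConfusionMatrix(tp=0, tn=5, fp=3, fn=2))
        assert report.precision == 0.0 and report.sensitivity == 0.0
        assert report.f1 == 0.0

    def test_empty_matrix_rejected(self):
        with pytest.raises(ParameterError):
            metrics(ConfusionMatrix(0, 0, 0, 0))

    def test_agrees_with_brute_force_recount_on_fuzzed_predictions(self):
        """1000 fuzzed label/prediction sets: formulas match a naive recount."""
        rng = np.random.default_rng(2024)
        for _ in range(1000):
            n = int(rng.integers(2, 40))
            y = rng.integers(0, 2, n)
            p = rng.integers(0, 2, n)
            cm = confusion(y, p)
            tp = sum(1 for a, b in zip(y, p) if a == 1 and b == 1)
            tn = sum(1 for a, b in zip(y, p) if a == 0 and b == 0)
            fp = sum(1 for a, b in zip(y, p) if a == 0 and b == 1)
            fn = sum(1 for a, b in zip(y, p) if a == 1 and b == 0)
            assert (cm.tp, cm.tn, cm.fp, cm.fn) == (tp, tn, fp, fn)
            report = metrics(cm)
            assert report.accuracy == pytest.approx((tp + tn) / n)
            if tp + fp:
                assert report.precision == pytest.approx(tp / (tp + fp))
            if tp + fn:
                assert report.sensitivity == pytest.approx(tp / (tp + fn))
            if tn + fp:
                assert report.specificity == pytest.approx(tn / (tn + fp))

    def test_accuracy_is_prevalence_weighted_mean_of_sens_and_spec(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            tp, tn, fp, fn = (int(v) for v in rng.integers(1, 50, 4))
            report = metrics(ConfusionMatrix(tp, tn, fp, fn))
            P, N = tp + fn, tn + fp
            weighted = (report.sensitivity * P + report.specificity * N) / (P + N)
            assert report.accuracy == pytest.approx(weighted, abs=1e-12)


class TestKFold:
    def test_145_samples_make_five_folds_of_29(self):
        folds = kfold(145, CVPlan(k=5, seed=0))
        assert [len(f) for f in folds] == [29] * 5

    def test_folds_partition_indices(self):
        folds = kfold(103, CVPlan(k=5, seed=3))
        flat = np.sort(np.concatenate(folds))
        assert np.array_equal(flat, np.arange(103))
        sizes = sorted(len(f) for f in folds)
        assert sizes[-1] - sizes[0] <= 1

    def test_infeasible_plans_rejected(self):
        with pytest.raises(PlanError):
            CVPlan(k=1)
        with pytest.raises(PlanError):
            kfold(3, CVPlan(k=5))


class TestROC:
    def test_perfect_and_reversed_separation(self):
        y = [0] * 5 + [1] * 5
        scores = np.arange(10.0)
        _, auc = roc(y, scores)
        assert auc == 1.0
        _, auc_rev = roc(y, -scores)
        assert auc_rev == 0.0

    def test_endpoints_and_monotonicity(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 200)
        s = rng.normal(size=200)
        points, _ = roc(y, s)
        assert tuple(points[0]) == (0.0, 0.0)
        assert tuple(points[-1]) == (1.0, 1.0)
        assert np.all(np.diff(points[:, 0]) >= 0)
        assert np.all(np.diff(points[:, 1]) >= 0)

    def test_invariant_under_monotone_score_transform(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, 300)
        s = rng.normal(size=300)
        _, auc = roc(y, s)
        _, auc_exp = roc(y, np.exp(s))
        assert auc == pytest.approx(auc_exp, abs=1e-12)

    def test_matches_sklearn_auc(self):
        rng = np.random.default_rng(2)
        y = rng.integers(0, 2, 500)
        s = rng.normal(size=500) + y  # informative scores
        _, auc = roc(y, s)
        assert auc == pytest.approx(roc_auc_score(y, s), abs=1e-12)

    def test_random_scores_give_chance_auc(self):
        rng = np.random.default_rng(3)
        y = rng.integers(0, 2, 10000)
        s = rng.normal(size=10000)
        _, auc = roc(y, s)
        assert auc == pytest.approx(0.5, abs=0.02)

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateROCError):
            roc([1, 1, 1], [0.1, 0.2, 0.3])


def rule_inputs(**overrides):
    base = {f"I{j}": 1 for j in range(1, 8)}
    base.update(overrides)
    return base


class TestRuleNetwork:
    def test_volume_rule_antecedent_gives_class_zero(self):
        decision = evaluate_rule_network(rule_inputs(I2=0, I7=0, I4=1, I6=1, I5=1))
        assert decision.klass == 0 and decision.matched

    def test_pressure_rule_antecedent_gives_class_one(self):
        decision = evaluate_rule_network(rule_inputs(I2=0, I7=0, I5=0, I4=0))
        assert decision.klass == 1 and decision.matched

    def test_unmatched_input_falls_back_to_default_with_flag(self):
        decision = evaluate_rule_network(rule_inputs(I2=1))
        assert decision.klass == RuleNetwork().default_class
        assert not decision.matched

    def test_total_function_over_binary_domain(self):
        """Every one of the 128 binary assignments maps to exactly one class."""
        from itertools import product

        for bits in product((0, 1), repeat=7):
            inputs = {f"I{j+1}": b for j, b in enumerate(bits)}
            decision = evaluate_rule_network(inputs)
            assert decision.klass in (0, 1)

    def test_hidden_node_inference(self):
        net = RuleNetwork()
        hidden = net.infer_hidden(rule_inputs(I2=0, I7=0, I5=0))
        assert hidden["H2"] == 0.0 and hidden["H3"] == -1.0
        assert hidden["H1"] is None  # never assigned by the published rules
        assert net.infer_outputs(hidden) == (1, 0)
        assert net.infer_outputs({"H1": None, "H2": 1.0, "H3": 1.0}) == (0, 1)

    def test_out_of_domain_input_rejected(self):
        with pytest.raises(DomainError, match="I3"):
            evaluate_rule_network(rule_inputs(I3=2))
        with pytest.raises(DomainError):
            evaluate_rule_network({"I1": 0})


class TestHarness:
    def test_separable_data_all_families_accurate(self, separable_results):
        for family, entry in separable_results.items():
            assert entry.report.accuracy >= 0.95, family
            assert entry.report.auc >= 0.95, family

    def test_permuted_labels_collapse_to_majority_rate(self, permuted_results, permuted_table):
        majority = max(
            permuted_table.labels.mean(), 1.0 - permuted_table.labels.mean()
        )
        for family, entry in permuted_results.items():
            assert abs(entry.report.accuracy - majority) < 0.05, family

    def test_confusion_counts_cover_test_split(self, separable_results, separable_table):
        n_test = separable_table.n_rows - round(separable_table.n_rows * 0.7)
        for entry in separable_results.values():
            assert entry.confusion.total == n_test

    def test_repeat_run_is_identical(self):
        table = generate(DatasetConfig(n_rows=400, effect_size=2.0, seed=9))
        a = run_benchmark(table, families=("DT", "NBT"), seed=9)
        b = run_benchmark(table, families=("DT", "NBT"), seed=9)
        for family in ("DT", "NBT"):
            assert a[family].confusion == b[family].confusion
            assert a[family].report.auc == b[family].report.auc
            assert a[family].best_params == b[family].best_params

    def test_unknown_family_and_empty_grid_rejected(self, separable_table):
        with pytest.raises(ConfigurationError):
            run_benchmark(separable_table, families=("SVM",))
        with pytest.raises(ConfigurationError):
            run_benchmark(separable_table, families=("DT",), grids={"DT": {}})
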