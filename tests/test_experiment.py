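"""Sampling, metrics, statistics, comparisons and hyper-parameter search."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from koti import (FewShotConfig, Method, Note, RunResult,
                  TinyMaskedLM, compare_methods, evaluate, holm_bonferroni,
                  paired_ttest, random_search, run_experiment,
                  sample_training_set)
from koti.experiment import ExperimentError, SamplingError
from koti.task_config import TaskSpec
from test_backend import separable_examples

SPEC3 = TaskSpec(name="t3", template_text="q: [MASK]",
                 classes=("a", "b", "c"),
                 label_words={"a": "wa", "b": "wb", "c": "wc"})
SPEC2 = TaskSpec(name="t2", template_text="q: [MASK]",
                 classes=("Yes", "Unmentioned"),
                 label_words={"Yes": "yes", "Unmentioned": "no"})


def pool_with_counts(counts):
    notes = []
    for cls, n in counts.items():
        notes.extend(Note(f"{cls}{i}", "x.", cls) for i in range(n))
    return notes


class TestSampler:
    def test_balanced_draws_exactly_k_per_class(self):
        pool = pool_with_counts({"a": 9, "b": 7, "c": 12})
        train, eval_set = sample_training_set(
            pool, FewShotConfig(strategy="balanced", k=4, seed=1), 0)
        labels = [n.label for n in train]
        assert len(train) == 12
        assert all(labels.count(c) == 4 for c in "abc")
        assert len(eval_set) == len(pool) - 12
        assert {n.id for n in train}.isdisjoint({n.id for n in eval_set})

    def test_random_matched_size_is_k_times_classes(self):
        pool = pool_with_counts({"a": 30, "b": 5, "c": 5})
        train, _ = sample_training_set(
            pool, FewShotConfig(strategy="random_matched", k=4, seed=1), 0)
        assert len(train) == 12

    def test_fixed_total_draws_n(self):
        pool = pool_with_counts({"a": 30, "b": 30})
        train, _ = sample_training_set(
            pool, FewShotConfig(strategy="fixed_total", k=50, seed=1), 0)
        assert len(train) == 50

    def test_same_seed_and_run_reproduce_the_split(self):
        pool = pool_with_counts({"a": 20, "b": 20})
        cfg = FewShotConfig(strategy="balanced", k=3, seed=9)
        first = sample_training_set(pool, cfg, 4)
        second = sample_training_set(pool, cfg, 4)
        assert [n.id for n in first[0]] == [n.id for n in second[0]]
        different = sample_training_set(pool, cfg, 5)
        assert [n.id for n in first[0]] != [n.id for n in different[0]]

    def test_underpopulated_class_names_the_class(self):
        pool = pool_with_counts({"a": 10, "rare": 2})
        with pytest.raises(SamplingError, match="rare"):
            sample_training_set(
                pool, FewShotConfig(strategy="balanced", k=4), 0)

    @settings(max_examples=200, derandomize=True)
    @given(counts=st.lists(st.integers(10, 30), min_size=2, max_size=4),
           k=st.sampled_from([1, 4, 10]), seed=st.integers(0, 99))
    def test_balanced_counts_hold_across_random_pools(self, counts, k,
                                                      seed):
        pool = pool_with_counts({f"c{i}": n for i, n in enumerate(counts)})
        train, _ = sample_training_set(
            pool, FewShotConfig(strategy="balanced", k=k, seed=seed), 0)
        labels = [n.label for n in train]
        assert len(train) == k * len(counts)
        assert all(labels.count(f"c{i}") == k for i in range(len(counts)))


class TestEvaluate:
    def test_perfect_predictions_score_one(self):
        golds = ["a", "b", "c", "a"]
        per_class, summary = evaluate(golds, golds, SPEC3)
        assert summary == 1.0
        assert all(v == (1.0, 1.0, 1.0) for v in per_class.values())

    def test_no_positive_predictions_give_zero_f1(self):
        per_class, summary = evaluate(
            ["Unmentioned"] * 4, ["Yes", "Yes", "Unmentioned",
                                  "Unmentioned"], SPEC2)
        assert per_class["Yes"] == (0.0, 0.0, 0.0)
        assert summary == 0.0  # binary summary = positive-class F1

    def test_macro_f1_matches_hand_computed_confusion_matrix(self):
        # confusion (rows gold a,b,c; cols pred): [[3,1,0],[1,2,1],[0,0,2]]
        golds = list("aaaabbbbcc")
        preds = list("aaababbccc")
        per_class, summary = evaluate(preds, golds, SPEC3)
        # hand: P_a=3/4, R_a=3/4, F_a=0.75; P_b=2/3, R_b=2/4, F_b=4/7
        # P_c=2/3, R_c=2/2, F_c=4/5
        assert per_class["a"][2] == pytest.approx(0.75)
        assert per_class["b"][2] == pytest.approx(4 / 7)
        assert per_class["c"][2] == pytest.approx(4 / 5)
        assert summary == pytest.approx((0.75 + 4 / 7 + 4 / 5) / 3,
                                        abs=1e-12)

    def test_label_outside_classes_is_rejected(self):
        with pytest.raises(ExperimentError):
            evaluate(["a"], ["z"], SPEC3)


class TestPairedTTest:
    def test_matches_independent_t_distribution_computation(self):
        a = [0.52, 0.61, 0.55, 0.70, 0.66]
        b = [0.48, 0.57, 0.56, 0.61, 0.60]
        d = np.array(a) - np.array(b)
        t = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        expected = 2 * stats.t.sf(abs(t), df=len(d) - 1)
        assert paired_ttest(a, b) == pytest.approx(expected, abs=1e-10)

    def test_identical_vectors_return_one(self):
        assert paired_ttest([0.1, 0.2, 0.3], [0.1, 0.2, 0.3]) == 1.0

    def test_constant_nonzero_difference_warns_and_returns_zero(self):
        with pytest.warns(UserWarning, match="constant"):
            p = paired_ttest([0.5, 0.6, 0.7], [0.4, 0.5, 0.6])
        assert p == 0.0

    def test_short_vectors_rejected(self):
        with pytest.raises(ExperimentError):
            paired_ttest([0.5], [0.4])


def holm_oracle(p_values, alpha):
    """Brute-force step-down: literal sequential rule on sorted ranks."""
    order = sorted(range(len(p_values)), key=lambda i: p_values[i])
    m = len(p_values)
    rejected = [False] * m
    for rank, idx in enumerate(order):
        if p_values[idx] <= alpha / (m - rank):
            rejected[idx] = True
        else:
            break
    return rejected


class TestHolmBonferroni:
    def test_family_of_five_most_stringent_threshold(self):
        thresholds, _ = holm_bonferroni([0.2, 0.3, 0.4, 0.5, 0.6],
                                        alpha=0.05)
        assert thresholds[0] == pytest.approx(0.01)
        assert thresholds == sorted(thresholds)

    def test_all_ones_reject_nothing(self):
        _, rejected = holm_bonferroni([1.0] * 4)
        assert rejected == [False] * 4

    def test_step_down_stops_at_first_failure(self):
        # sorted: 0.001 <= .0125, 0.004 <= .0167, then 0.03 > .025 stops
        # the walk, so 0.03 and 0.9 stay accepted
        _, rejected = holm_bonferroni([0.03, 0.001, 0.004, 0.9],
                                      alpha=0.05)
        assert rejected == [False, True, True, False]

    @settings(max_examples=300, derandomize=True)
    @given(p=st.lists(st.floats(0, 1), min_size=1, max_size=6),
           alpha=st.sampled_from([0.01, 0.05, 0.1]))
    def test_matches_brute_force_oracle(self, p, alpha):
        _, rejected = holm_bonferroni(p, alpha)
        assert rejected == holm_oracle(p, alpha)


def runs(method, task, f1s):
    return [RunResult(method=method, task=task, run_index=i, n_train=4,
                      per_class={}, summary_f1=f)
            for i, f in enumerate(f1s)]


class TestCompareMethods:
    def test_delta_and_percent_change_arithmetic(self):
        res = compare_methods(
            runs("koti", "t", [0.70, 0.74]) + runs("koti", "u",
                                                   [0.80, 0.90]),
            runs("sti-s", "t", [0.57, 0.63]) + runs("sti-s", "u",
                                                    [0.62, 0.68]))
        row = res.rows[0]  # task 't': 0.72 vs 0.60
        assert row.delta_f1 == pytest.approx(0.12)
        assert row.percent_change == pytest.approx(20.0)
        assert res.overall is not None
        assert res.overall.delta_f1 == pytest.approx(
            (0.72 + 0.85) / 2 - (0.60 + 0.65) / 2)

    def test_identical_results_give_zero_delta_p_one(self):
        a = runs("koti", "t", [0.5, 0.6, 0.7])
        b = runs("sti-k", "t", [0.5, 0.6, 0.7])
        res = compare_methods(a, b)
        assert res.rows[0].delta_f1 == 0.0
        assert res.rows[0].p_value == 1.0
        assert res.rejected == (False,)

    def test_zero_baseline_reports_missing_percent(self):
        a = runs("koti", "t", [0.2, 0.25, 0.3])
        b = runs("sti-s", "t", [0.0, 0.0, 0.0])
        res = compare_methods(a, b)
        assert res.rows[0].percent_change is None
        assert res.rows[0].delta_f1 == pytest.approx(0.25)

    def test_task_pairing_uses_per_task_means(self):
        f1s = {"p": 0.60, "q": 0.70, "r": 0.55, "s": 0.80, "t": 0.65}
        a = sum((runs("koti", t, [f, f + 0.1]) for t, f in f1s.items()), [])
        b = sum((runs("sti-k", t, [0.5, 0.52]) for t in f1s), [])
        res = compare_methods(a, b, pairing="tasks")
        assert len(res.rows) == 1 and res.rows[0].task == "all"
        assert res.overall is None
        assert res.rows[0].delta_f1 == pytest.approx(
            np.mean([f + 0.05 for f in f1s.values()]) - 0.51)

    def test_mismatched_tasks_rejected(self):
        with pytest.raises(ExperimentError):
            compare_methods(runs("koti", "t", [0.5, 0.6]),
                            runs("sti-k", "u", [0.5, 0.6]))


class TestRandomSearch:
    def test_single_combination_space_returns_it(self):
        result = random_search(
            {"learning_rate": [0.01], "epochs": [2]}, n_draws=3,
            evaluate_draw=lambda cfg, i: [0.5], seed=0)
        assert result.best.learning_rate == 0.01
        assert result.best.epochs == 2

    def test_same_seed_gives_identical_draw_sequence(self):
        space = {"learning_rate": [0.1, 0.01, 0.001],
                 "batch_size": [2, 4, 8]}
        seen = []
        for _ in range(2):
            result = random_search(space, n_draws=5,
                                   evaluate_draw=lambda cfg, i: [0.0],
                                   seed=42)
            seen.append([entry["config"] for entry in result.log])
        assert seen[0] == seen[1]

    def test_dominant_configuration_is_selected(self):
        """Training for 10 epochs dominates not training at all on
        separable data; the search must find it."""
        from koti import finetune as finetune_fn

        examples, verb, tok = separable_examples(n=20, seed=2)

        def evaluate_draw(cfg, draw_index):
            model = TinyMaskedLM(vocab_size=tok.vocab_size, seed=0)
            model, _ = finetune_fn(model, examples, cfg, verb)
            hits = 0
            for pinput, gold in examples:
                logits = model.score(pinput)
                pred = max(verb.class_order,
                           key=lambda c: logits[verb.class_token[c]])
                hits += pred == gold
            return [hits / len(examples)]

        result = random_search({"epochs": [0, 10]}, n_draws=4,
                               evaluate_draw=evaluate_draw, seed=1)
        assert result.best.epochs == 10

    def test_empty_space_rejected(self):
        with pytest.raises(ExperimentError):
            random_search({}, 1, lambda c, i: [0.0])


class TestRunExperiment:
    def test_zero_shot_is_a_single_untrained_run(self, small_cfg):
        from conftest import mock_setup

        corpus, notes, spec, tok, backend = mock_setup(small_cfg,
                                                       model_max=512)
        res = run_experiment(spec, notes, Method.KOTI, backend, tok,
                             model_max=512)
        assert len(res.results) == 1
        assert res.results[0].n_train == 0

    def test_few_shot_produces_distinct_runs(self, small_cfg):
        from conftest import mock_setup

        corpus, notes, spec, tok, backend = mock_setup(small_cfg,
                                                       model_max=512)
        few = FewShotConfig(strategy="balanced", k=1, runs=4, seed=0)
        res = run_experiment(spec, notes, Method.KOTI, backend, tok,
                             model_max=512, few_shot=few)
        assert len(res.results) == 4
        assert [r.run_index for r in res.results] == [0, 1, 2, 3]
        assert all(r.n_train == 3 for r in res.results)
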