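"""Task orchestration: label mapping, splits, CV, evaluation, cascade, ablation."""

import random
from collections import Counter

import numpy as np
import pytest

from carestrat import default_spec, generate_corpus
from carestrat.corpus import StrategyRecord
from carestrat.features import FeatureConfig
from carestrat.labels import ClassLabel
from carestrat.models import train_majority
from carestrat.experiments import (
    EXCLUDED,
    CvSpec,
    ModelConfig,
    ablation,
    apply_task,
    cascade_predict,
    cv_partitions,
    evaluate,
    fit_candidate,
    repeated_stratified_cv,
    run_cascade,
    run_experiment,
    stratified_split,
    stratified_test_counts,
    task_labels,
)
from carestrat.synthetic import spec_with
from carestrat.preprocess import preprocess_corpus, PreprocessConfig

from .oracles import metrics_by_hand

L = ClassLabel
TABLE1 = {L.ENV: 975, L.SELF: 307, L.PREF: 84, L.COMP: 104, L.NONSTRAT: 106}


class TestTaskLabels:
    def test_env_is_extrinsic_under_task2(self):
        assert task_labels(L.ENV, 2) == "EXTRINSIC"

    def test_nonstrat_excluded_from_task3(self):
        assert task_labels(L.NONSTRAT, 3) == EXCLUDED

    def test_task1_groups_all_strategy_classes(self):
        for lab in (L.ENV, L.SELF, L.PREF, L.COMP):
            assert task_labels(lab, 1) == "STRATEGY"
        assert task_labels(L.NONSTRAT, 1) == "NONSTRAT"

    def test_task2_totals_from_published_counts(self):
        mapped = Counter()
        for lab, n in TABLE1.items():
            mapped[task_labels(lab, 2)] += n
        assert mapped["EXTRINSIC"] == 975
        assert mapped["INTRINSIC"] == 495

    def test_task4_is_identity(self):
        for lab in L:
            assert task_labels(lab, 4) == lab.value

    def test_unknown_task_or_label_raise(self):
        with pytest.raises(ValueError):
            task_labels(L.ENV, 9)
        with pytest.raises(ValueError):
            task_labels("bogus", 1)


class TestStratifiedSplit:
    def test_published_five_class_test_counts(self):
        counts = stratified_test_counts({lab.value: n for lab, n in TABLE1.items()})
        assert counts == {"ENV": 195, "SELF": 61, "PREF": 17, "COMP": 21, "NONSTRAT": 21}
        assert sum(counts.values()) == 315

    def test_task2_and_task3_denominators(self):
        assert stratified_test_counts({"EXTRINSIC": 975, "INTRINSIC": 495}) == {
            "EXTRINSIC": 195,
            "INTRINSIC": 99,
        }
        t3 = stratified_test_counts({"SELF": 307, "PREF": 84, "COMP": 104})
        assert t3 == {"SELF": 61, "PREF": 17, "COMP": 21}
        assert sum(t3.values()) == 99

    def test_exact_fifth_of_small_stratum(self):
        assert stratified_test_counts({"only": 10}) == {"only": 2}

    def test_zero_stratum_raises(self):
        with pytest.raises(ValueError):
            stratified_test_counts({"a": 10, "b": 0})

    def test_split_disjoint_exhaustive_and_counts(self):
        rng = random.Random(0)
        labels = [rng.choice("abc") for _ in range(97)]
        train, test = stratified_split(labels, seed=1)
        assert len(set(train) & set(test)) == 0
        assert sorted(np.concatenate([train, test]).tolist()) == list(range(97))
        expected = stratified_test_counts(dict(Counter(labels)))
        observed = Counter(labels[i] for i in test)
        assert dict(observed) == expected

    def test_split_depends_on_seed_not_on_call_order(self):
        labels = ["a"] * 40 + ["b"] * 10
        t1 = stratified_split(labels, seed=3)[1]
        t2 = stratified_split(labels, seed=3)[1]
        t3 = stratified_split(labels, seed=4)[1]
        assert np.array_equal(t1, t2)
        assert not np.array_equal(t1, t3)


class TestEvaluate:
    def test_perfect_predictions(self):
        rep = evaluate(["a", "b", "a"], ["a", "b", "a"])
        assert rep.accuracy == 1.0
        assert rep.macro_f1 == pytest.approx(1.0)

    def test_hand_computed_confusion(self):
        # confusion [[2,1],[0,3]] on gold a,a,a,b,b,b
        gold = ["a", "a", "a", "b", "b", "b"]
        pred = ["a", "a", "b", "b", "b", "b"]
        rep = evaluate(pred, gold)
        assert rep.accuracy == pytest.approx(5 / 6)
        assert rep.per_class["a"]["f1"] == pytest.approx(0.8)
        assert rep.per_class["b"]["f1"] == pytest.approx(6 / 7)
        assert rep.macro_f1 == pytest.approx((0.8 + 6 / 7) / 2)
        assert rep.confusion.tolist() == [[2, 1], [0, 3]]

    def test_matches_hand_formulas_on_random_label_lists(self):
        rng = random.Random(2)
        for _ in range(100):
            classes = ["a", "b", "c"][: rng.randint(2, 3)]
            n = rng.randint(3, 15)
            gold = [rng.choice(classes) for _ in range(n)]
            pred = [rng.choice(classes) for _ in range(n)]
            rep = evaluate(pred, gold, classes=classes)
            acc, per_class, macro = metrics_by_hand(gold, pred, classes)
            assert rep.accuracy == pytest.approx(acc)
            for c in classes:
                p, r, f = per_class[c]
                assert rep.per_class[c]["precision"] == pytest.approx(p)
                assert rep.per_class[c]["recall"] == pytest.approx(r)
                assert rep.per_class[c]["f1"] == pytest.approx(f)
            assert rep.macro_f1 == pytest.approx(macro[2])

    def test_unpredicted_gold_class_contributes_zero_f1(self):
        rep = evaluate(["a", "a", "a"], ["a", "a", "b"], classes=["a", "b"])
        assert rep.per_class["b"]["f1"] == 0.0
        assert rep.macro_f1 == pytest.approx(rep.per_class["a"]["f1"] / 2)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            evaluate(["a"], ["a", "b"])


class TestCrossValidation:
    def _task2_data(self, corpus):
        records, labels = apply_task(corpus, 2)
        tokens = [
            ts.tokens for ts in preprocess_corpus(records, PreprocessConfig())
        ]
        return tokens, labels

    def test_single_candidate_returned_unconditionally(self, small_corpus):
        tokens, labels = self._task2_data(small_corpus)
        cand = [(FeatureConfig(), ModelConfig(family="majority"))]
        res = repeated_stratified_cv(tokens, labels, cand, CvSpec(folds=3, repeats=1))
        assert res.best_index == 0

    def test_each_record_in_exactly_one_validation_fold_per_repeat(self):
        labels = ["a"] * 30 + ["b"] * 20
        seen = {0: [], 1: []}
        for rep, _tr, va in cv_partitions(labels, folds=5, repeats=2, seed=0):
            seen[rep].extend(va.tolist())
        for rep in (0, 1):
            assert sorted(seen[rep]) == list(range(50))

    def test_svm_tfidf_outranks_majority_on_discriminative_corpus(self):
        spec = spec_with(
            default_spec(seed=11),
            class_counts={L.ENV: 60, L.SELF: 60, L.PREF: 0, L.COMP: 0, L.NONSTRAT: 0},
            discriminability=0.9,
        )
        corpus = generate_corpus(spec)
        tokens, labels = self._task2_data(corpus)
        candidates = [
            (FeatureConfig(base="tfidf"), ModelConfig(family="majority")),
            (FeatureConfig(base="tfidf"), ModelConfig(family="svm")),
        ]
        res = repeated_stratified_cv(
            tokens, labels, candidates, CvSpec(folds=5, repeats=2, seed=0)
        )
        assert res.best_index == 1
        assert res.mean_accuracy[1] > res.mean_accuracy[0]

    def test_fold_reduction_warns(self):
        tokens = [["a"]] * 20 + [["b"]] * 4
        labels = ["x"] * 20 + ["y"] * 4
        cand = [(FeatureConfig(), ModelConfig(family="majority"))]
        with pytest.warns(UserWarning, match="reducing folds"):
            repeated_stratified_cv(tokens, labels, cand, CvSpec(folds=10, repeats=1))

    def test_no_candidates_raise(self):
        with pytest.raises(ValueError):
            repeated_stratified_cv([["a"]], ["x"], [], CvSpec())


class TestRunExperiment:
    SVM = [(FeatureConfig(base="tfidf"), ModelConfig(family="svm"))]
    MAJ = [(FeatureConfig(base="tfidf"), ModelConfig(family="majority"))]

    def test_task_without_in_scope_records_raises(self):
        corpus = [StrategyRecord("1", "none", L.NONSTRAT)]
        with pytest.raises(ValueError):
            run_experiment(corpus, 3, self.SVM)

    def test_same_seeds_give_identical_reports(self, small_corpus):
        r1 = run_experiment(small_corpus, 2, self.SVM, split_seed=5)
        r2 = run_experiment(small_corpus, 2, self.SVM, split_seed=5)
        assert r1.report.to_dict() == r2.report.to_dict()

    def test_svm_beats_majority_baseline(self, small_corpus):
        svm = run_experiment(small_corpus, 1, self.SVM, split_seed=0)
        maj = run_experiment(small_corpus, 1, self.MAJ, split_seed=0)
        assert svm.report.accuracy > maj.report.accuracy

    def test_majority_accuracy_equals_majority_test_share(self, small_corpus):
        res = run_experiment(small_corpus, 4, self.MAJ, split_seed=0)
        counts = res.provenance["test_class_counts"]
        assert res.report.accuracy == pytest.approx(
            max(counts.values()) / sum(counts.values())
        )

    def test_no_leak_test_set_never_touches_fitting(self, small_corpus):
        records, labels = apply_task(small_corpus, 2)
        train_idx, test_idx = stratified_split(labels, seed=0)
        train_tokens = [
            ts.tokens
            for ts in preprocess_corpus(
                [records[i] for i in train_idx], PreprocessConfig()
            )
        ]
        train_labels = [labels[i] for i in train_idx]
        cfg = FeatureConfig(base="tfidf", use_pmi=True, pmi_min_count=1)
        f1 = fit_candidate(cfg, ModelConfig(family="svm"), train_tokens, train_labels)
        f2 = fit_candidate(cfg, ModelConfig(family="svm"), train_tokens, train_labels)
        assert f1.pipeline.base_model.vocabulary == f2.pipeline.base_model.vocabulary
        assert f1.pipeline.pmi_lexicon.word_sets == f2.pipeline.pmi_lexicon.word_sets
        assert np.array_equal(f1.model.weights, f2.model.weights)


class TestCascade:
    def test_stage1_stop_skips_later_stages(self):
        calls = []

        def stage(name, answer):
            def _f(tokens):
                calls.append(name)
                return answer

            return _f

        out = cascade_predict(
            ["none"], stage("s1", "NONSTRAT"), stage("s2", "EXTRINSIC"), stage("s3", "SELF")
        )
        assert out == "NONSTRAT"
        assert calls == ["s1"]

    def test_stage2_stop_maps_to_env(self):
        out = cascade_predict(
            ["quiet"], lambda t: "STRATEGY", lambda t: "EXTRINSIC", lambda t: "SELF"
        )
        assert out == "ENV"

    def test_missing_stage_raises(self):
        with pytest.raises(ValueError):
            cascade_predict(["x"], lambda t: "STRATEGY", None, lambda t: "SELF")

    def test_oracle_stages_reproduce_gold_labels(self, small_corpus):
        gold = {tuple(r.text.split()): r.label for r in small_corpus}

        def oracle(task):
            def _f(tokens):
                return task_labels(gold[tuple(tokens)], task)

            return _f

        tokens = [tuple(r.text.split()) for r in small_corpus]
        preds = run_cascade(tokens, oracle(1), oracle(2), oracle(3))
        assert preds == [r.label.value for r in small_corpus]

    def test_majority_stages_label_everything_env(self, default_corpus):
        # modal stage labels under the published counts: STRATEGY, then EXTRINSIC
        stage1 = train_majority([task_labels(r.label, 1) for r in default_corpus])
        stage2_labels = [
            task_labels(r.label, 2)
            for r in default_corpus
            if task_labels(r.label, 2) != EXCLUDED
        ]
        stage2 = train_majority(stage2_labels)
        stage3 = train_majority(
            [
                task_labels(r.label, 3)
                for r in default_corpus
                if task_labels(r.label, 3) != EXCLUDED
            ]
        )
        preds = run_cascade(
            [r.text.split() for r in default_corpus[:50]],
            lambda t: stage1.stored_label,
            lambda t: stage2.stored_label,
            lambda t: stage3.stored_label,
        )
        assert set(preds) == {"ENV"}


class TestAblation:
    def test_report_shape_and_not_applicable_rows(self, small_corpus):
        cfg = FeatureConfig(base="tfidf", use_concepts=True, use_pmi=True)
        rep = ablation(small_corpus, 1, cfg, ModelConfig(family="svm"), split_seed=0)
        assert len(rep.rows) == 5  # full + four toggles
        by_name = {r.name: r for r in rep.rows}
        assert by_name["full"].applicable
        assert by_name["without concept"].applicable
        assert not by_name["without pos"].applicable
        assert by_name["without pos"].accuracy_pct is None

    def test_class_aligned_concepts_do_not_hurt_on_average(self):
        # low-discriminability corpora: concept triggers carry class signal
        full_scores, ablated_scores = [], []
        for seed in range(5):
            spec = spec_with(
                default_spec(seed=seed),
                class_counts={
                    L.ENV: 60, L.SELF: 60, L.PREF: 0, L.COMP: 0, L.NONSTRAT: 0,
                },
                discriminability=0.3,
            )
            corpus = generate_corpus(spec)
            cfg = FeatureConfig(base="tfidf", use_concepts=True)
            rep = ablation(corpus, 2, cfg, ModelConfig(family="svm"), split_seed=seed)
            by_name = {r.name: r for r in rep.rows}
            full_scores.append(by_name["full"].accuracy_pct)
            ablated_scores.append(by_name["without concept"].accuracy_pct)
        assert np.mean(ablated_scores) <= np.mean(full_scores)
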