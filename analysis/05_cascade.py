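#!/usr/bin/env python
"""Compare cascaded (tasks 1-2-3) against flat five-way classification.

Trains an SVM + TF-IDF stage model for each of the three pipeline stages on
the shared training set, runs the cascade on the held-out test set, and
scores the resulting five-way labels against the flat task-4 model on the
same split.
"""

import argparse
from collections import Counter
from pathlib import Path

import pandas as pd

from carestrat import default_spec, generate_corpus
from carestrat.experiments import (
    EXCLUDED,
    ModelConfig,
    evaluate,
    fit_candidate,
    run_cascade,
    run_experiment,
    stage_predictor,
    stratified_split,
    task_classes,
    task_labels,
)
from carestrat.features import FeatureConfig
from carestrat.preprocess import (
    PreprocessConfig,
    dictionary_from_corpus,
    preprocess_corpus,
)

SVM = (FeatureConfig(base="tfidf"), ModelConfig(family="svm"))


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=42)
    parser.add_argument("--out", type=Path, default=Path("results"))
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    corpus = generate_corpus(default_spec(seed=args.seed))
    labels5 = [r.label.value for r in corpus]
    train_idx, test_idx = stratified_split(labels5, seed=args.seed)
    train_recs = [corpus[i] for i in train_idx]
    test_recs = [corpus[i] for i in test_idx]

    dictionary, freqs = dictionary_from_corpus([r.text for r in train_recs])
    pp = PreprocessConfig(dictionary=dictionary, token_frequencies=freqs)
    train_tokens = [s.tokens for s in preprocess_corpus(train_recs, pp)]
    test_tokens = [s.tokens for s in preprocess_corpus(test_recs, pp)]

    stages = []
    for task in (1, 2, 3):
        pairs = [
            (toks, task_labels(rec.label, task))
            for toks, rec in zip(train_tokens, train_recs)
            if task_labels(rec.label, task) != EXCLUDED
        ]
        fitted = fit_candidate(SVM[0], SVM[1], [p[0] for p in pairs], [p[1] for p in pairs])
        stages.append(stage_predictor(fitted))

    cascade_preds = run_cascade(test_tokens, *stages)
    gold = [r.label.value for r in test_recs]
    cascade_report = evaluate(cascade_preds, gold, classes=task_classes(4))
    flat = run_experiment(corpus, 4, [SVM], split_seed=args.seed)

    table = pd.DataFrame(
        [
            {
                "approach": "cascade (tasks 1-2-3)",
                "accuracy_pct": cascade_report.accuracy_pct,
                "macro_f1": cascade_report.macro_f1_2dp,
            },
            {
                "approach": "flat five-way (task 4)",
                "accuracy_pct": flat.report.accuracy_pct,
                "macro_f1": flat.report.macro_f1_2dp,
            },
        ]
    )
    table.to_csv(args.out / "cascade_vs_flat.csv", index=False)
    print(table.to_string(index=False))
    errs = Counter(
        (g, p) for g, p in zip(gold, cascade_preds) if g != p
    )
    print("\nCascade confusions (gold -> predicted):", dict(errs) or "none")


if __name__ == "__main__":
    main()
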