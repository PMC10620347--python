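#!/usr/bin/env python
"""Train the classifier families on the synthetic corpus across all four tasks.

For each task, evaluates logistic regression, naive Bayes and the linear SVM
on the TF-IDF base representation, without and with the hand-crafted blocks
(POS/dependency tag counts, PMI likely-word-set counts, concept features),
next to the majority baseline — the synthetic analogue of the study's model
comparison table. Paragraph-vector columns are optional (``--embeddings``)
because PV-DM training dominates runtime.

A YAML candidate grid (see carestrat.config) can replace the built-in
candidates via ``--config``.
"""

import argparse
from pathlib import Path

import pandas as pd

from carestrat import default_spec, generate_corpus
from carestrat.config import load_experiment_config
from carestrat.experiments import ModelConfig, run_experiment
from carestrat.features import FeatureConfig


def built_in_candidates(embeddings: bool):
    bases = ["tfidf"] + (["doc2vec"] if embeddings else [])
    out = []
    for base in bases:
        plain = FeatureConfig(base=base)
        added = FeatureConfig(
            base=base, use_pos=True, use_dep=True, use_pmi=True, use_concepts=True
        )
        for family in ("logistic", "naive_bayes", "svm"):
            out.append((f"{family}, {base}", plain, ModelConfig(family=family)))
            out.append((f"{family}, {base}+features", added, ModelConfig(family=family)))
    out.append(("majority", FeatureConfig(), ModelConfig(family="majority")))
    return out


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=42)
    parser.add_argument("--out", type=Path, default=Path("results"))
    parser.add_argument("--embeddings", action="store_true",
                        help="also evaluate paragraph-vector columns (slow)")
    parser.add_argument("--config", type=Path, default=None,
                        help="YAML candidate grid instead of the built-in one")
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    corpus = generate_corpus(default_spec(seed=args.seed))
    if args.config is not None:
        cfg = load_experiment_config(args.config)
        candidates = [
            (f"candidate {i}", f, m) for i, (f, m) in enumerate(cfg["candidates"])
        ]
    else:
        candidates = built_in_candidates(args.embeddings)

    rows = []
    for task in (1, 2, 3, 4):
        for name, fcfg, mcfg in candidates:
            res = run_experiment(corpus, task, [(fcfg, mcfg)], split_seed=args.seed)
            rows.append(
                {
                    "task": task,
                    "configuration": name,
                    "accuracy_pct": res.report.accuracy_pct,
                    "macro_f1": res.report.macro_f1_2dp,
                }
            )
            print(f"task {task} | {name:28s} acc={rows[-1]['accuracy_pct']:6.2f} "
                  f"F1={rows[-1]['macro_f1']:.2f}")
    table = pd.DataFrame(rows)
    table.to_csv(args.out / "model_performance.csv", index=False)
    best = table.loc[table.groupby("task")["accuracy_pct"].idxmax()]
    print("\nBest configuration per task:")
    print(best.to_string(index=False))
    print(
        "\nOn synthetic corpora the class signal is lexical by construction, "
        "so TF-IDF with a linear model saturates; the hand-crafted blocks "
        "matter mainly when lexical discriminability is lowered."
    )


if __name__ == "__main__":
    main()
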