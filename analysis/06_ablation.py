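#!/usr/bin/env python
"""Feature ablation for the strategy/non-strategy filter (task 1).

Starts from the full configuration (TF-IDF base plus concept, POS,
dependency and PMI likely-word-set blocks) on the linear SVM and toggles one
hand-crafted block off at a time, mirroring the study's feature-performance
table layout.
"""

import argparse
from pathlib import Path

import pandas as pd

from carestrat import default_spec, generate_corpus
from carestrat.experiments import ModelConfig, ablation
from carestrat.features import FeatureConfig


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=42)
    parser.add_argument("--task", type=int, default=1, choices=(1, 2, 3, 4))
    parser.add_argument("--out", type=Path, default=Path("results"))
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    corpus = generate_corpus(default_spec(seed=args.seed))
    full = FeatureConfig(
        base="tfidf", use_pos=True, use_dep=True, use_pmi=True, use_concepts=True
    )
    report = ablation(
        corpus, args.task, full, ModelConfig(family="svm"), split_seed=args.seed
    )
    table = pd.DataFrame(
        [
            {
                "configuration": row.name,
                "accuracy_pct": row.accuracy_pct,
                "macro_f1": row.macro_f1,
            }
            for row in report.rows
        ]
    )
    table.to_csv(args.out / f"ablation_task{args.task}.csv", index=False)
    print(table.to_string(index=False))
    print(
        "\nEach row removes exactly one hand-crafted block from the full "
        "configuration; on the default synthetic corpus lexical TF-IDF signal "
        "dominates, so ablations move accuracy only marginally."
    )


if __name__ == "__main__":
    main()
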