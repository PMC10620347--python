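#!/usr/bin/env python
"""Majority baselines and split denominators for the four classification tasks.

These quantities are pure split arithmetic over the class counts, so on the
default corpus they reproduce the study's printed baselines: accuracies
93.33 / 66.33 / 61.62 / 61.90 (the last is 195/315; the study prints 61.91)
and test denominators 21 non-strategies, 99 intrinsic, 17 preferences.
"""

import argparse
from pathlib import Path

import pandas as pd

from carestrat import default_spec, generate_corpus
from carestrat.experiments import ModelConfig, run_experiment
from carestrat.features import FeatureConfig

MAJ = [(FeatureConfig(), ModelConfig(family="majority"))]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=42)
    parser.add_argument("--out", type=Path, default=Path("results"))
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    corpus = generate_corpus(default_spec(seed=args.seed))
    rows = []
    for task in (1, 2, 3, 4):
        res = run_experiment(corpus, task, MAJ, split_seed=args.seed)
        rows.append(
            {
                "task": task,
                "n_train": res.provenance["n_train"],
                "n_test": res.provenance["n_test"],
                "test_class_counts": res.provenance["test_class_counts"],
                "baseline_accuracy_pct": res.report.accuracy_pct,
                "baseline_macro_f1": res.report.macro_f1_2dp,
            }
        )
    table = pd.DataFrame(rows)
    table.to_csv(args.out / "baselines.csv", index=False)
    print(table.to_string(index=False))
    print(
        "\nBaseline accuracies are the majority stratum's test share under "
        "largest-remainder 80/20 allocation; they depend only on the class "
        "counts, not on the seed or the text."
    )


if __name__ == "__main__":
    main()
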