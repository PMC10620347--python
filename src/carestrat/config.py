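"""YAML experiment configuration.

A config file holds a list of candidate configurations plus optional split
and cross-validation settings:

.. code-block:: yaml

    candidates:
      - features: {base: tfidf, use_pos: true, use_pmi: true}
        model: {family: svm, C: 1.0}
      - features: {base: tfidf}
        model: {family: naive_bayes}
    cv: {folds: 10, repeats: 3, seed: 0}
    split_seed: 0
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .experiments import CvSpec, ModelConfig
from .features import FeatureConfig
from .models import LogisticConfig


def feature_config_from_dict(d: dict) -> FeatureConfig:
    return FeatureConfig(**d)


def model_config_from_dict(d: dict) -> ModelConfig:
    d = dict(d)
    logistic = d.pop("logistic", None)
    if logistic is not None:
        d["logistic"] = LogisticConfig(**logistic)
    return ModelConfig(**d)


def load_experiment_config(path: str | Path) -> dict:
    """Parse a YAML config into candidates, CvSpec and split seed."""
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    candidates = [
        (
            feature_config_from_dict(c.get("features", {})),
            model_config_from_dict(c.get("model", {})),
        )
        for c in raw.get("candidates", [])
    ]
    if not candidates:
        raise ValueError(f"{path}: no candidates defined")
    cv = CvSpec(**raw.get("cv", {}))
    return {
        "candidates": candidates,
        "cv": cv,
        "split_seed": int(raw.get("split_seed", 0)),
    }
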