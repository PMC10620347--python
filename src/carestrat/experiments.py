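"""Task orchestration: splits, cross-validated model selection, evaluation.

Four classification tasks over the five-way label scheme:

1. strategy vs non-strategy (binary, all records);
2. extrinsic vs intrinsic (binary, strategy records only);
3. sense of self / preferences / activity competence (intrinsic records);
4. flat five-way classification.

The corpus is split once into a fixed 80/20 stratified train/test partition
using largest-remainder per-stratum allocation — the rule that reproduces the
published test denominators (21 non-strategies, 99 intrinsic, 17 preferences)
exactly from the published class counts. Model selection uses repeated
stratified 10-fold cross-validation on the training set only, with all
feature fitting confined to each training fold; the winner is refit on the
full training set and evaluated once on the held-out test set.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Callable, Hashable, Iterable, Sequence

import numpy as np
from sklearn.metrics import confusion_matrix, precision_recall_fscore_support
from sklearn.model_selection import StratifiedKFold

from .corpus import Corpus
from .features import FeatureConfig, FeaturePipeline
from .labels import ClassLabel, INTRINSIC_CLASSES, STRATEGY_CLASSES
from .lexicon import ConceptLexicon
from .models import (
    LogisticConfig,
    train_linear_svm,
    train_logistic,
    train_majority,
    train_naive_bayes,
)
from .preprocess import PreprocessConfig, dictionary_from_corpus, preprocess_corpus

#: Sentinel for records outside a task's scope.
EXCLUDED = "EXCLUDED"

TASK_IDS = (1, 2, 3, 4)

_TASK_CLASSES: dict[int, tuple[str, ...]] = {
    1: ("NONSTRAT", "STRATEGY"),
    2: ("EXTRINSIC", "INTRINSIC"),
    3: ("COMP", "PREF", "SELF"),
    4: ("COMP", "ENV", "NONSTRAT", "PREF", "SELF"),
}


def task_classes(task: int) -> tuple[str, ...]:
    if task not in _TASK_CLASSES:
        raise ValueError(f"unknown task id: {task!r}")
    return _TASK_CLASSES[task]


def task_labels(label: ClassLabel, task: int) -> str:
    """Map a five-way gold label onto the task's label space (or EXCLUDED)."""
    if not isinstance(label, ClassLabel):
        raise ValueError(f"unknown label: {label!r}")
    if task == 1:
        return "STRATEGY" if label in STRATEGY_CLASSES else "NONSTRAT"
    if task == 2:
        if label is ClassLabel.NONSTRAT:
            return EXCLUDED
        return "INTRINSIC" if label in INTRINSIC_CLASSES else "EXTRINSIC"
    if task == 3:
        return label.value if label in INTRINSIC_CLASSES else EXCLUDED
    if task == 4:
        return label.value
    raise ValueError(f"unknown task id: {task!r}")


def apply_task(corpus: Corpus, task: int) -> tuple[Corpus, list[str]]:
    """Filter the corpus to the task's scope and map labels."""
    records, labels = [], []
    for rec in corpus:
        lab = task_labels(rec.label, task)
        if lab != EXCLUDED:
            records.append(rec)
            labels.append(lab)
    if not records:
        raise ValueError(f"task {task} has no in-scope records in this corpus")
    return records, labels


# ---------------------------------------------------------------------------
# Fixed stratified 80/20 split (largest-remainder allocation)


@dataclass(frozen=True)
class SplitSpec:
    test_fraction: float = 0.2
    seed: int = 0


def stratified_test_counts(
    stratum_sizes: dict[Hashable, int], test_fraction: float = 0.2
) -> dict[Hashable, int]:
    """Largest-remainder rounding of ``test_fraction x stratum size``.

    Floors first, then +1 to the strata with the largest fractional
    remainders (ties: larger remainder, then label order) until the rounded
    global total is reached.
    """
    for stratum, size in stratum_sizes.items():
        if size <= 0:
            raise ValueError(f"stratum {stratum!r} has no records")
    total = sum(stratum_sizes.values())
    target = int(math.floor(test_fraction * total + 0.5))
    quotas = {s: test_fraction * n for s, n in stratum_sizes.items()}
    counts = {s: int(math.floor(q)) for s, q in quotas.items()}
    remaining = target - sum(counts.values())
    order = sorted(
        stratum_sizes,
        key=lambda s: (-(quotas[s] - counts[s]), str(s)),
    )
    i = 0
    while remaining > 0 and i < len(order):
        s = order[i]
        if counts[s] < stratum_sizes[s]:
            counts[s] += 1
            remaining -= 1
        i += 1
    if remaining != 0:
        raise ValueError("could not allocate the requested test fraction")
    return counts


def stratified_split(
    labels: Sequence[Hashable],
    test_fraction: float = 0.2,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Disjoint, exhaustive train/test index arrays; membership uniform per stratum."""
    labels = list(labels)
    sizes = Counter(labels)
    counts = stratified_test_counts(dict(sizes), test_fraction)
    rng = np.random.default_rng(seed)
    test_idx: list[int] = []
    for stratum in sorted(sizes, key=str):
        members = np.array([i for i, lab in enumerate(labels) if lab == stratum])
        chosen = rng.choice(members, size=counts[stratum], replace=False)
        test_idx.extend(int(i) for i in chosen)
    test = np.array(sorted(test_idx), dtype=int)
    mask = np.ones(len(labels), dtype=bool)
    mask[test] = False
    train = np.flatnonzero(mask)
    return train, test


# ---------------------------------------------------------------------------
# Metrics


@dataclass(frozen=True)
class MetricsReport:
    """Accuracy, per-class and macro precision/recall/F1, confusion matrix."""

    labels: tuple[str, ...]
    accuracy: float
    per_class: dict[str, dict[str, float]]
    macro_precision: float
    macro_recall: float
    macro_f1: float
    confusion: np.ndarray  # gold rows x predicted columns

    @property
    def accuracy_pct(self) -> float:
        """Accuracy as a percentage, rounded to two decimals (report format)."""
        return round(100.0 * self.accuracy, 2)

    @property
    def macro_f1_2dp(self) -> float:
        return round(self.macro_f1, 2)

    def to_dict(self) -> dict:
        return {
            "labels": list(self.labels),
            "accuracy": self.accuracy,
            "accuracy_pct": self.accuracy_pct,
            "per_class": self.per_class,
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
            "confusion": self.confusion.tolist(),
        }


def evaluate(
    predicted: Sequence[Hashable],
    gold: Sequence[Hashable],
    classes: Sequence[Hashable] | None = None,
) -> MetricsReport:
    """Score predictions against gold labels.

    Macro averages run over the task's gold classes (``classes`` if given,
    else the classes present in ``gold``): a class never predicted still
    contributes its zero F1. Zero denominators follow the 0-convention.
    """
    if len(predicted) != len(gold):
        raise ValueError(
            f"length mismatch: {len(predicted)} predictions vs {len(gold)} gold labels"
        )
    order = [str(c) for c in (classes if classes is not None else sorted(set(gold), key=str))]
    gold_s = [str(g) for g in gold]
    pred_s = [str(p) for p in predicted]
    prec, rec, f1, _ = precision_recall_fscore_support(
        gold_s, pred_s, labels=order, zero_division=0
    )
    cm_order = order + sorted({p for p in pred_s} - set(order))
    cm = confusion_matrix(gold_s, pred_s, labels=cm_order)
    per_class = {
        lab: {"precision": float(p), "recall": float(r), "f1": float(f)}
        for lab, p, r, f in zip(order, prec, rec, f1)
    }
    correct = sum(p == g for p, g in zip(pred_s, gold_s))
    return MetricsReport(
        labels=tuple(cm_order),
        accuracy=correct / len(gold_s),
        per_class=per_class,
        macro_precision=float(np.mean(prec)),
        macro_recall=float(np.mean(rec)),
        macro_f1=float(np.mean(f1)),
        confusion=cm,
    )


# ---------------------------------------------------------------------------
# Model/candidate configuration and fitting


@dataclass(frozen=True)
class ModelConfig:
    """One classifier family plus its hyperparameters."""

    family: str = "svm"  # majority | naive_bayes | logistic | svm
    C: float = 1.0
    logistic: LogisticConfig = field(default_factory=LogisticConfig)

    def __post_init__(self) -> None:
        if self.family not in ("majority", "naive_bayes", "logistic", "svm"):
            raise ValueError(f"unknown model family: {self.family!r}")


@dataclass
class FittedCandidate:
    """A trained (feature pipeline, model) pair operating on token sequences."""

    feature_config: FeatureConfig
    model_config: ModelConfig
    pipeline: FeaturePipeline | None
    model: object

    def predict(self, token_sequences: Sequence[Iterable[str]]) -> list:
        docs = [list(t) for t in token_sequences]
        family = self.model_config.family
        if family == "majority":
            return self.model.predict(docs)
        if family == "naive_bayes":
            return self.model.predict(docs)
        X = self.pipeline.transform(docs)
        return self.model.predict(X)


def fit_candidate(
    feature_config: FeatureConfig,
    model_config: ModelConfig,
    train_tokens: Sequence[Iterable[str]],
    train_labels: Sequence,
    lexicon: ConceptLexicon | None = None,
) -> FittedCandidate:
    """Fit every representation and the model on training data only.

    The majority baseline ignores features; naive Bayes trains on the token
    sequences themselves (its bag-of-words event model), independent of the
    configured base representation.
    """
    docs = [list(t) for t in train_tokens]
    family = model_config.family
    pipeline = None
    if family == "majority":
        model = train_majority(list(train_labels))
    elif family == "naive_bayes":
        model = train_naive_bayes(docs, list(train_labels))
    else:
        pipeline = FeaturePipeline(feature_config, lexicon=lexicon)
        pipeline.fit(docs, list(train_labels))
        X = pipeline.transform(docs)
        if family == "logistic":
            model = train_logistic(X, list(train_labels), model_config.logistic)
        else:
            model = train_linear_svm(X, list(train_labels), C=model_config.C)
    return FittedCandidate(feature_config, model_config, pipeline, model)


# ---------------------------------------------------------------------------
# Repeated stratified cross-validated selection


@dataclass(frozen=True)
class CvSpec:
    folds: int = 10
    repeats: int = 3
    seed: int = 0
    metric: str = "accuracy"  # selection metric; macro-F1 breaks ties


@dataclass(frozen=True)
class CvResult:
    best_index: int
    mean_accuracy: tuple[float, ...]
    mean_macro_f1: tuple[float, ...]
    folds_used: int


def cv_partitions(
    labels: Sequence, folds: int, repeats: int, seed: int
) -> Iterable[tuple[int, np.ndarray, np.ndarray]]:
    """Yield ``(repeat, train_idx, val_idx)``; each repeat is a fresh partition."""
    y = np.array([str(lab) for lab in labels])
    for rep in range(repeats):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed + rep)
        for tr, va in skf.split(np.zeros(len(y)), y):
            yield rep, tr, va


def repeated_stratified_cv(
    train_tokens: Sequence[Iterable[str]],
    train_labels: Sequence,
    candidates: Sequence[tuple[FeatureConfig, ModelConfig]],
    cv: CvSpec = CvSpec(),
    lexicon: ConceptLexicon | None = None,
) -> CvResult:
    """Score every candidate by mean fold accuracy; pick the argmax.

    Each repeat is a distinct stratified partition into ``folds`` folds; all
    feature fitting happens inside each training fold. Ties break by mean
    macro-F1, then by candidate order. Folds are reduced (with a warning)
    when the smallest stratum has fewer than ``folds`` records.
    """
    if not candidates:
        raise ValueError("repeated_stratified_cv requires at least one candidate")
    docs = [list(t) for t in train_tokens]
    labels = list(train_labels)
    min_stratum = min(Counter(labels).values())
    folds = min(cv.folds, min_stratum)
    if folds < 2:
        raise ValueError("smallest stratum has <2 records; cannot stratify folds")
    if folds < cv.folds:
        warnings.warn(
            f"reducing folds from {cv.folds} to {folds}: smallest stratum has "
            f"{min_stratum} records",
            stacklevel=2,
        )
    acc = np.zeros((len(candidates), cv.repeats * folds))
    mf1 = np.zeros_like(acc)
    col = 0
    for _rep, tr, va in cv_partitions(labels, folds, cv.repeats, cv.seed):
        for ci, (fcfg, mcfg) in enumerate(candidates):
            fitted = fit_candidate(
                fcfg, mcfg, [docs[i] for i in tr], [labels[i] for i in tr], lexicon
            )
            preds = fitted.predict([docs[i] for i in va])
            report = evaluate(preds, [labels[i] for i in va])
            acc[ci, col] = report.accuracy
            mf1[ci, col] = report.macro_f1
        col += 1
    mean_acc = acc.mean(axis=1)
    mean_f1 = mf1.mean(axis=1)
    best = min(
        range(len(candidates)), key=lambda i: (-mean_acc[i], -mean_f1[i], i)
    )
    return CvResult(
        best_index=best,
        mean_accuracy=tuple(float(a) for a in mean_acc),
        mean_macro_f1=tuple(float(f) for f in mean_f1),
        folds_used=folds,
    )


# ---------------------------------------------------------------------------
# End-to-end experiment


@dataclass
class ExperimentResult:
    report: MetricsReport
    fitted: FittedCandidate
    provenance: dict


def run_experiment(
    corpus: Corpus,
    task: int,
    candidates: Sequence[tuple[FeatureConfig, ModelConfig]],
    split_seed: int = 0,
    cv: CvSpec = CvSpec(),
    lexicon: ConceptLexicon | None = None,
    test_fraction: float = 0.2,
) -> ExperimentResult:
    """Split once, select via CV on train, refit the winner, evaluate on test."""
    records, labels = apply_task(corpus, task)
    train_idx, test_idx = stratified_split(labels, test_fraction, seed=split_seed)
    train_recs = [records[i] for i in train_idx]
    test_recs = [records[i] for i in test_idx]
    train_labels = [labels[i] for i in train_idx]
    test_labels = [labels[i] for i in test_idx]

    dictionary, freqs = dictionary_from_corpus([r.text for r in train_recs])
    pp_config = PreprocessConfig(dictionary=dictionary, token_frequencies=freqs)
    train_tokens = [ts.tokens for ts in preprocess_corpus(train_recs, pp_config)]
    test_tokens = [ts.tokens for ts in preprocess_corpus(test_recs, pp_config)]

    if len(candidates) == 1:
        best_index, cv_result = 0, None
    else:
        cv_result = repeated_stratified_cv(train_tokens, train_labels, candidates, cv, lexicon)
        best_index = cv_result.best_index
    fcfg, mcfg = candidates[best_index]
    fitted = fit_candidate(fcfg, mcfg, train_tokens, train_labels, lexicon)
    preds = fitted.predict(test_tokens)
    report = evaluate(preds, test_labels, classes=task_classes(task))
    provenance = {
        "task": task,
        "split_seed": split_seed,
        "test_fraction": test_fraction,
        "n_train": len(train_recs),
        "n_test": len(test_recs),
        "train_class_counts": dict(Counter(train_labels)),
        "test_class_counts": dict(Counter(test_labels)),
        "cv": None if cv_result is None else vars(cv_result) | {"spec": vars(cv)},
        "chosen_candidate": best_index,
        "feature_config": vars(fcfg),
        "model_config": {"family": mcfg.family, "C": mcfg.C},
    }
    return ExperimentResult(report=report, fitted=fitted, provenance=provenance)


# ---------------------------------------------------------------------------
# Cascaded (pipelined) inference: tasks 1 -> 2 -> 3

StagePredictor = Callable[[Sequence[str]], str]


def cascade_predict(
    tokens: Sequence[str],
    stage1: StagePredictor,
    stage2: StagePredictor,
    stage3: StagePredictor,
) -> str:
    """Five-way label via the pipelined tasks; later stages are skipped after a stop.

    Stage 1 predicting NONSTRAT stops with NONSTRAT; stage 2 predicting
    EXTRINSIC stops with ENV; otherwise stage 3 returns SELF/PREF/COMP.
    """
    for stage in (stage1, stage2, stage3):
        if stage is None:
            raise ValueError("cascade requires all three stage models")
    if stage1(tokens) == "NONSTRAT":
        return "NONSTRAT"
    if stage2(tokens) == "EXTRINSIC":
        return "ENV"
    return stage3(tokens)


def run_cascade(
    token_sequences: Sequence[Sequence[str]],
    stage1: StagePredictor,
    stage2: StagePredictor,
    stage3: StagePredictor,
) -> list[str]:
    return [cascade_predict(toks, stage1, stage2, stage3) for toks in token_sequences]


def stage_predictor(fitted: FittedCandidate) -> StagePredictor:
    """Adapt a fitted candidate to the single-document cascade interface."""

    def _predict(tokens: Sequence[str]) -> str:
        return str(fitted.predict([list(tokens)])[0])

    return _predict


# ---------------------------------------------------------------------------
# Feature ablation


@dataclass(frozen=True)
class AblationRow:
    name: str
    applicable: bool
    accuracy_pct: float | None
    macro_f1: float | None


@dataclass(frozen=True)
class AblationReport:
    task: int
    rows: tuple[AblationRow, ...]


_ABLATION_BLOCKS = (
    ("concept", "use_concepts"),
    ("pos", "use_pos"),
    ("dep", "use_dep"),
    ("pmi", "use_pmi"),
)


def ablation(
    corpus: Corpus,
    task: int,
    feature_config: FeatureConfig,
    model_config: ModelConfig,
    split_seed: int = 0,
    lexicon: ConceptLexicon | None = None,
) -> AblationReport:
    """Full configuration plus one row per hand-crafted block toggled off.

    Blocks disabled in the base configuration cannot be toggled and are
    reported as not applicable.
    """
    full = run_experiment(
        corpus, task, [(feature_config, model_config)], split_seed=split_seed, lexicon=lexicon
    )
    rows = [AblationRow("full", True, full.report.accuracy_pct, full.report.macro_f1_2dp)]
    for name, flag in _ABLATION_BLOCKS:
        if not getattr(feature_config, flag):
            rows.append(AblationRow(f"without {name}", False, None, None))
            continue
        variant = replace(feature_config, **{flag: False})
        res = run_experiment(
            corpus, task, [(variant, model_config)], split_seed=split_seed, lexicon=lexicon
        )
        rows.append(
            AblationRow(f"without {name}", True, res.report.accuracy_pct, res.report.macro_f1_2dp)
        )
    return AblationReport(task=task, rows=tuple(rows))
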