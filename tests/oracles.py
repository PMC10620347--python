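"""Independent oracle implementations used by unit and acceptance tests.

Each oracle recomputes a quantity from its defining formula or by exhaustive
search, sharing no code with the implementation it checks.
"""

from __future__ import annotations

import math
from functools import lru_cache

import numpy as np


def levenshtein_recursive(a: str, b: str) -> int:
    """Edit distance by the textbook recursion (memoized, not the DP table)."""

    @lru_cache(maxsize=None)
    def d(i: int, j: int) -> int:
        if i == 0:
            return j
        if j == 0:
            return i
        return min(
            d(i - 1, j) + 1,
            d(i, j - 1) + 1,
            d(i - 1, j - 1) + (a[i - 1] != b[j - 1]),
        )

    return d(len(a), len(b))


def pmi_direct(n_wc: int, n_w: int, n_c: int, total: int, n_words: int,
               n_classes: int, alpha: float) -> float:
    """PMI straight from the smoothed-probability formula."""
    denom = total + alpha * n_words * n_classes
    p_wc = (n_wc + alpha) / denom
    p_w = (n_w + alpha * n_classes) / denom
    p_c = (n_c + alpha * n_words) / denom
    return math.log(p_wc / (p_w * p_c))


def nb_log_joint_brute(train_docs, train_labels, test_tokens):
    """Per-class log P(c) + sum log P(w|c) with add-one smoothing, by direct counting.

    Unknown test tokens (outside the training vocabulary) are removed.
    Returns (sorted class list, scores).
    """
    classes = sorted(set(train_labels), key=str)
    vocab = sorted({t for doc in train_docs for t in doc})
    scores = []
    for c in classes:
        class_docs = [doc for doc, lab in zip(train_docs, train_labels) if lab == c]
        prior = len(class_docs) / len(train_docs)
        class_tokens = [t for doc in class_docs for t in doc]
        score = math.log(prior)
        for tok in test_tokens:
            if tok not in vocab:
                continue
            count = sum(t == tok for t in class_tokens)
            score += math.log((count + 1) / (len(class_tokens) + len(vocab)))
        scores.append(score)
    return classes, np.array(scores)


def metrics_by_hand(gold, predicted, classes):
    """Accuracy and per-class/macro precision, recall, F1 from the definitions."""
    per_class = {}
    for c in classes:
        tp = sum(g == c and p == c for g, p in zip(gold, predicted))
        fp = sum(g != c and p == c for g, p in zip(gold, predicted))
        fn = sum(g == c and p != c for g, p in zip(gold, predicted))
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / (tp + fn) if tp + fn else 0.0
        f1 = (
            2 * precision * recall / (precision + recall)
            if precision + recall
            else 0.0
        )
        per_class[c] = (precision, recall, f1)
    accuracy = sum(g == p for g, p in zip(gold, predicted)) / len(gold)
    macro = tuple(
        sum(per_class[c][i] for c in classes) / len(classes) for i in range(3)
    )
    return accuracy, per_class, macro


def svm_primal_objective(w: float, b: float, x: np.ndarray, y: np.ndarray,
                         C: float) -> float:
    """Binary 1-D primal hinge objective (1/2)w^2 + C sum hinge."""
    hinge = np.maximum(0.0, 1.0 - y * (w * x + b)).sum()
    return 0.5 * w * w + C * hinge


def svm_grid_search(x: np.ndarray, y: np.ndarray, C: float,
                    lim: float = 3.0, step: float = 0.01):
    """Dense grid search over (w, b) for the 1-D binary hinge objective."""
    grid = np.arange(-lim, lim + step / 2, step)
    best = (np.inf, 0.0, 0.0)
    for w in grid:
        margins = 1.0 - y * (w * x[None, :] + grid[:, None])
        obj = 0.5 * w * w + C * np.maximum(0.0, margins).sum(axis=1)
        i = int(np.argmin(obj))
        if obj[i] < best[0]:
            best = (float(obj[i]), float(w), float(grid[i]))
    return best  # (objective, w, b)
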