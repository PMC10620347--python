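"""Pointwise mutual information between words and classes.

PMI(w, c) = ln p(w,c) / (p(w) p(c)), estimated from token-level
word-by-class counts with additive smoothing ``alpha`` applied to the joint
counts and propagated consistently to the marginals:

    p(w,c) = (n(w,c) + a) / (N + a|W||C|)
    p(w)   = (n(w) + a|C|) / (N + a|W||C|)
    p(c)   = (n(c) + a|W|) / (N + a|W||C|)

Natural log throughout; the features only use PMI rankings, which any log
base preserves. The per-class "likely word sets" are the top-k words by PMI
among words seen at least ``min_count`` times — built from training data
only.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Hashable, Iterable, Sequence

import numpy as np


@dataclass
class PmiTable:
    """Word-by-class token counts with smoothing constant alpha."""

    joint: dict[tuple[str, Hashable], int]
    word_counts: dict[str, int]
    class_counts: dict[Hashable, int]
    total: int
    alpha: float = 0.5

    @property
    def n_words(self) -> int:
        return len(self.word_counts)

    @property
    def n_classes(self) -> int:
        return len(self.class_counts)


def build_pmi_table(
    token_sequences: Sequence[Iterable[str]],
    labels: Sequence[Hashable],
    alpha: float = 0.5,
) -> PmiTable:
    if len(token_sequences) != len(labels):
        raise ValueError("token_sequences and labels differ in length")
    joint: Counter = Counter()
    words: Counter = Counter()
    classes: Counter = Counter()
    for toks, label in zip(token_sequences, labels):
        for tok in toks:
            joint[(tok, label)] += 1
            words[tok] += 1
            classes[label] += 1
    return PmiTable(
        joint=dict(joint),
        word_counts=dict(words),
        class_counts=dict(classes),
        total=sum(words.values()),
        alpha=alpha,
    )


def pmi(word: str, cls: Hashable, table: PmiTable) -> float:
    """Smoothed natural-log PMI of a word/class pair."""
    n_w = table.word_counts.get(word, 0)
    n_c = table.class_counts.get(cls, 0)
    a = table.alpha
    if a == 0.0 and (n_w == 0 or n_c == 0):
        raise ValueError(
            f"PMI undefined for unseen word/class ({word!r}, {cls!r}) with alpha=0"
        )
    denom = table.total + a * table.n_words * table.n_classes
    p_wc = (table.joint.get((word, cls), 0) + a) / denom
    p_w = (n_w + a * table.n_classes) / denom
    p_c = (n_c + a * table.n_words) / denom
    return math.log(p_wc / (p_w * p_c))


@dataclass(frozen=True)
class PmiLexicon:
    """Per-class ranked likely word sets (built on training folds only)."""

    word_sets: dict[Hashable, tuple[str, ...]]
    k: int

    @property
    def classes(self) -> list:
        return sorted(self.word_sets, key=str)


def build_likely_word_sets(
    token_sequences: Sequence[Iterable[str]],
    labels: Sequence[Hashable],
    k: int = 20,
    min_count: int = 2,
    alpha: float = 0.5,
    classes: Sequence[Hashable] | None = None,
) -> PmiLexicon:
    """Top-k PMI words per class; ties by frequency then lexicographic.

    ``classes`` defaults to the labels present in training; a requested class
    absent from the training data raises a ``ValueError`` naming it.
    """
    table = build_pmi_table(token_sequences, labels, alpha=alpha)
    wanted = list(classes) if classes is not None else sorted(table.class_counts, key=str)
    for cls in wanted:
        if cls not in table.class_counts:
            raise ValueError(f"class {cls!r} absent from training data")
    eligible = [w for w, n in table.word_counts.items() if n >= min_count]
    sets: dict[Hashable, tuple[str, ...]] = {}
    for cls in wanted:
        ranked = sorted(
            eligible,
            key=lambda w: (-pmi(w, cls, table), -table.word_counts[w], w),
        )
        sets[cls] = tuple(ranked[: max(k, 0)])
    return PmiLexicon(word_sets=sets, k=k)


def likely_set_features(tokens: Iterable[str], lexicon: PmiLexicon) -> np.ndarray:
    """One count per class: tokens falling in that class's likely word set."""
    toks = list(tokens)
    vec = np.zeros(len(lexicon.word_sets))
    for i, cls in enumerate(lexicon.classes):
        members = set(lexicon.word_sets[cls])
        vec[i] = sum(t in members for t in toks)
    return vec
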