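"""Synthetic caregiver-strategy corpus generator.

The study corpus (1,576 caregiver utterances annotated into five classes) is
not public; only aggregate statistics are printed: per-class record counts
975/307/84/104/106, per-class mean utterance lengths 7.20/6.60/7.64/5.85/5.21
tokens, corpus totals of 10,804 tokens and 2,337 vocabulary types. This module
samples corpora calibrated to those aggregates, with class-discriminative
vocabulary so the classification tasks are learnable, plus the surface noise
the real data exhibits (misspellings, personal names, digits, punctuation,
stopwords, one-word refusals in the non-strategy class).

Record lengths follow a shifted Poisson, ``1 + Poisson(mean - 1)``: positive,
integer, mean-matched. Each content token comes from the record's class
keyword pool with probability ``discriminability``, otherwise from the shared
class-neutral vocabulary; ``discriminability = 0`` therefore makes the
class-conditional content distributions identical by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .corpus import Corpus, StrategyRecord
from .labels import ClassLabel
from .vocab import (
    CLASS_KEYWORDS,
    FIRST_NAMES,
    OPENERS,
    REFUSAL_TEMPLATES,
    shared_vocabulary,
)

# A small set of function words woven into utterances as "stopword" noise.
_STOPWORD_NOISE = (
    "the", "a", "to", "and", "of", "in", "on", "for", "with", "at", "it",
    "this", "so", "her", "his", "them",
)

_PUNCT_MARKS = (".", "!", ",", "?")


@dataclass(frozen=True)
class NoiseRates:
    """Per-token surface-noise probabilities."""

    misspell_prob: float = 0.05
    name_prob: float = 0.05
    number_prob: float = 0.05
    punct_prob: float = 0.05
    stopword_prob: float = 0.05

    def validate(self) -> None:
        for name, p in vars(self).items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"noise rate {name}={p} outside [0, 1]")


@dataclass(frozen=True)
class CorpusSpec:
    """Parameters of one synthetic corpus draw.

    Defaults (via :func:`default_spec`) reproduce the published aggregates;
    ``class_keywords`` may override the built-in pools (used by tests to prove
    construction-level invariants).
    """

    class_counts: dict[ClassLabel, int]
    mean_lengths: dict[ClassLabel, float]
    shared_vocab_size: int = 2000
    keywords_per_class: int = 40
    discriminability: float = 0.8
    noise_rates: NoiseRates = field(default_factory=NoiseRates)
    refusal_prob: float = 0.5
    seed: int = 42
    class_keywords: dict[ClassLabel, tuple[str, ...]] | None = None

    def validate(self) -> None:
        for label in ClassLabel:
            if label not in self.class_counts:
                raise ValueError(f"class_counts missing {label}")
            if self.class_counts[label] < 0:
                raise ValueError(f"negative count for {label}")
            if label not in self.mean_lengths or self.mean_lengths[label] < 1.0:
                raise ValueError(f"mean length for {label} must be >= 1")
        if not 0.0 <= self.discriminability <= 1.0:
            raise ValueError("discriminability outside [0, 1]")
        if not 0.0 <= self.refusal_prob <= 1.0:
            raise ValueError("refusal_prob outside [0, 1]")
        if self.shared_vocab_size < 1:
            raise ValueError("shared_vocab_size must be >= 1")
        if self.keywords_per_class < 0:
            raise ValueError("keywords_per_class must be >= 0")
        self.noise_rates.validate()
        for label, pool in self.keyword_pools().items():
            if self.keywords_per_class > 0 and len(pool) == 0:
                raise ValueError(f"empty keyword pool for {label}")

    def keyword_pools(self) -> dict[ClassLabel, tuple[str, ...]]:
        pools = self.class_keywords if self.class_keywords is not None else CLASS_KEYWORDS
        return {
            label: tuple(pools.get(label, ()))[: self.keywords_per_class]
            for label in ClassLabel
        }

    @property
    def total_count(self) -> int:
        return sum(self.class_counts.values())


def default_spec(seed: int = 42) -> CorpusSpec:
    """Corpus specification matching the published per-class aggregates."""
    return CorpusSpec(
        class_counts={
            ClassLabel.ENV: 975,
            ClassLabel.SELF: 307,
            ClassLabel.PREF: 84,
            ClassLabel.COMP: 104,
            ClassLabel.NONSTRAT: 106,
        },
        mean_lengths={
            ClassLabel.ENV: 7.20,
            ClassLabel.SELF: 6.60,
            ClassLabel.PREF: 7.64,
            ClassLabel.COMP: 5.85,
            ClassLabel.NONSTRAT: 5.21,
        },
        seed=seed,
    )


def _draw_length(rng: np.random.Generator, mean: float) -> int:
    return 1 + int(rng.poisson(max(mean - 1.0, 0.0)))


def _misspell(rng: np.random.Generator, word: str) -> str:
    """One random character-level perturbation (insert/delete/replace/swap)."""
    letters = "abcdefghijklmnopqrstuvwxyz"
    if len(word) < 2:
        return word + letters[int(rng.integers(26))]
    op = int(rng.integers(4))
    i = int(rng.integers(len(word)))
    if op == 0:  # insert
        return word[:i] + letters[int(rng.integers(26))] + word[i:]
    if op == 1 and len(word) > 2:  # delete
        return word[:i] + word[i + 1 :]
    if op == 2:  # replace
        return word[:i] + letters[int(rng.integers(26))] + word[i + 1 :]
    # swap adjacent
    i = min(i, len(word) - 2)
    return word[:i] + word[i + 1] + word[i] + word[i + 2 :]


def _nonrefusal_mean(spec: CorpusSpec) -> float:
    """Mean length for sampled (non-template) NONSTRAT records.

    Chosen so the class mean including fixed refusal templates matches the
    configured mean; clamped at 1.
    """
    target = spec.mean_lengths[ClassLabel.NONSTRAT]
    r = spec.refusal_prob
    if r >= 1.0:
        return 1.0
    refusal_mean = float(np.mean([len(t.split()) for t in REFUSAL_TEMPLATES]))
    return max((target - r * refusal_mean) / (1.0 - r), 1.0)


def generate_corpus(spec: CorpusSpec) -> Corpus:
    """Sample a labeled corpus; identical seeds give identical corpora."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    shared = shared_vocabulary(spec.shared_vocab_size)
    pools = spec.keyword_pools()
    nr = spec.noise_rates
    records: Corpus = []
    counter = 0
    for label in ClassLabel:
        pool = pools[label]
        n = spec.class_counts[label]
        mean = spec.mean_lengths[label]
        if label is ClassLabel.NONSTRAT:
            mean = _nonrefusal_mean(spec)
        for _ in range(n):
            counter += 1
            rec_id = f"rec-{counter:05d}"
            if label is ClassLabel.NONSTRAT and rng.random() < spec.refusal_prob:
                text = REFUSAL_TEMPLATES[int(rng.integers(len(REFUSAL_TEMPLATES)))]
                records.append(StrategyRecord(rec_id, text, label))
                continue
            length = _draw_length(rng, mean)
            tokens: list[str] = []
            for pos in range(length):
                r = rng.random()
                if r < nr.name_prob:
                    tok = FIRST_NAMES[int(rng.integers(len(FIRST_NAMES)))]
                elif r < nr.name_prob + nr.number_prob:
                    tok = str(int(rng.integers(1, 60)))
                elif r < nr.name_prob + nr.number_prob + nr.stopword_prob:
                    tok = _STOPWORD_NOISE[int(rng.integers(len(_STOPWORD_NOISE)))]
                elif pos == 0 and rng.random() < 0.5:
                    tok = OPENERS[int(rng.integers(len(OPENERS)))]
                else:
                    # strictly-less: discriminability 0 never consults the pool
                    if pool and rng.random() < spec.discriminability:
                        tok = pool[int(rng.integers(len(pool)))]
                    else:
                        tok = shared[int(rng.integers(len(shared)))]
                    if rng.random() < nr.misspell_prob:
                        tok = _misspell(rng, tok)
                if rng.random() < nr.punct_prob:
                    tok = tok + _PUNCT_MARKS[int(rng.integers(len(_PUNCT_MARKS)))]
                tokens.append(tok)
            tokens[0] = tokens[0][:1].upper() + tokens[0][1:]
            records.append(StrategyRecord(rec_id, " ".join(tokens), label))
    return records


@dataclass(frozen=True)
class CorpusStats:
    """Token-level summary of a corpus under a given tokenizer."""

    n_documents: int
    n_tokens: int
    vocab_size: int
    mean_length_overall: float
    mean_length_per_class: dict[ClassLabel, float]


def corpus_stats(records: Corpus, tokenizer=str.split) -> CorpusStats:
    """Document/token/vocabulary counts and mean lengths (overall, per class)."""
    if not records:
        raise ValueError("corpus_stats requires a non-empty corpus")
    vocab: set[str] = set()
    n_tokens = 0
    per_class_tokens: dict[ClassLabel, int] = {}
    per_class_docs: dict[ClassLabel, int] = {}
    for rec in records:
        toks = tokenizer(rec.text)
        n_tokens += len(toks)
        vocab.update(toks)
        per_class_tokens[rec.label] = per_class_tokens.get(rec.label, 0) + len(toks)
        per_class_docs[rec.label] = per_class_docs.get(rec.label, 0) + 1
    means = {
        label: per_class_tokens[label] / per_class_docs[label]
        for label in per_class_docs
    }
    return CorpusStats(
        n_documents=len(records),
        n_tokens=n_tokens,
        vocab_size=len(vocab),
        mean_length_overall=n_tokens / len(records),
        mean_length_per_class=means,
    )


def spec_with(spec: CorpusSpec, **changes) -> CorpusSpec:
    """Functional update helper (frozen dataclass)."""
    return replace(spec, **changes)
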