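"""TF-IDF document representation.

Dialect (fixed, recorded in the model): vocabulary is the ``max_terms`` most
frequent training terms (ties lexicographic); ``idf(t) = ln((1+N)/(1+df(t))) + 1``
with N the number of training documents; document vectors are raw term
frequency times idf, L2-normalized; out-of-vocabulary tokens are ignored.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

DIALECT = "tf * (ln((1+N)/(1+df)) + 1), L2-normalized"


@dataclass
class TfidfModel:
    vocabulary: list[str]  # ordered, rank = frequency order
    document_frequency: dict[str, int]
    n_train_docs: int
    dialect: str = DIALECT
    _index: dict[str, int] = field(default_factory=dict, repr=False)
    _idf: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self._index = {t: i for i, t in enumerate(self.vocabulary)}
        df = np.array([self.document_frequency[t] for t in self.vocabulary], dtype=float)
        self._idf = np.log((1.0 + self.n_train_docs) / (1.0 + df)) + 1.0

    @property
    def dim(self) -> int:
        return len(self.vocabulary)

    def idf(self, term: str) -> float:
        return float(self._idf[self._index[term]])


def fit_tfidf(
    train_token_sequences: Sequence[Iterable[str]], max_terms: int = 5000
) -> TfidfModel:
    """Fit vocabulary and document frequencies on training documents only."""
    docs = [list(toks) for toks in train_token_sequences]
    if not docs:
        raise ValueError("cannot fit TF-IDF on an empty training set")
    freq: Counter[str] = Counter()
    df: Counter[str] = Counter()
    for toks in docs:
        freq.update(toks)
        df.update(set(toks))
    # most frequent first; ties lexicographic
    ranked = sorted(freq, key=lambda t: (-freq[t], t))[:max_terms]
    return TfidfModel(
        vocabulary=ranked,
        document_frequency={t: df[t] for t in ranked},
        n_train_docs=len(docs),
    )


def transform(model: TfidfModel, tokens: Iterable[str]) -> np.ndarray:
    """Encode one document as a dense L2-normalized tf-idf vector."""
    vec = np.zeros(model.dim)
    for tok in tokens:
        i = model._index.get(tok)
        if i is not None:
            vec[i] += 1.0
    vec *= model._idf
    norm = np.linalg.norm(vec)
    if norm > 0:
        vec /= norm
    return vec


def transform_many(model: TfidfModel, docs: Sequence[Iterable[str]]) -> np.ndarray:
    return np.stack([transform(model, toks) for toks in docs]) if docs else np.zeros((0, model.dim))


def write_tfidf(model: TfidfModel, path) -> None:
    """Serialize as a TSV vocabulary table (term, rank, document frequency)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# n_train_docs={model.n_train_docs}\tdialect={model.dialect}\n")
        fh.write("term\trank\tdocument_frequency\n")
        for rank, term in enumerate(model.vocabulary):
            fh.write(f"{term}\t{rank}\t{model.document_frequency[term]}\n")
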