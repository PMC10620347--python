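"""Paragraph-vector document embeddings (distributed-memory variant).

Each document owns a trainable vector that is averaged with the input vectors
of the words inside a symmetric context window to predict the center word;
training uses negative sampling over a unigram^0.75 noise distribution with a
linearly decaying learning rate. Inference freezes the word and output
matrices and trains only a fresh document vector, so inferred vectors are
deterministic given the model seed.

Single-threaded numpy implementation; defaults follow the study setup
(dimension 100, minimum count 1, 30 epochs, window 5).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np


def _sigmoid(x: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30.0, 30.0)))


@dataclass
class DocEmbeddingModel:
    dim: int
    min_count: int
    epochs: int
    window: int
    negative: int
    seed: int
    vocab: dict[str, int]
    word_vectors: np.ndarray  # (V, dim) input vectors
    output_weights: np.ndarray  # (V, dim)
    doc_vectors: np.ndarray  # (n_train_docs, dim)
    noise_cdf: np.ndarray = field(repr=False, default=None)
    alpha: float = 0.025
    min_alpha: float = 1e-4


def _train_doc(
    tokens: list[int],
    doc_vec: np.ndarray,
    word_in: np.ndarray,
    word_out: np.ndarray,
    noise_cdf: np.ndarray,
    rng: np.random.Generator,
    window: int,
    negative: int,
    lr: float,
    update_words: bool,
    update_outputs: bool = True,
) -> None:
    n = len(tokens)
    for i, center in enumerate(tokens):
        lo, hi = max(0, i - window), min(n, i + window + 1)
        context = [tokens[j] for j in range(lo, hi) if j != i]
        n_inputs = len(context) + 1
        h = (doc_vec + word_in[context].sum(axis=0)) / n_inputs if context else doc_vec.copy()
        negs = np.searchsorted(noise_cdf, rng.random(negative))
        grad_h = np.zeros_like(h)
        for target, label in [(center, 1.0)] + [(int(t), 0.0) for t in negs]:
            if label == 0.0 and target == center:
                continue
            f = _sigmoid(h @ word_out[target])
            g = lr * (label - f)
            grad_h += g * word_out[target]
            if update_outputs:
                word_out[target] += g * h
        grad_h /= n_inputs
        doc_vec += grad_h
        if update_words and context:
            for w in context:
                word_in[w] += grad_h


def fit_doc_embeddings(
    train_token_sequences: Sequence[Iterable[str]],
    dim: int = 100,
    min_count: int = 1,
    epochs: int = 30,
    seed: int = 0,
    window: int = 5,
    negative: int = 5,
) -> DocEmbeddingModel:
    """Train paragraph vectors on the training documents."""
    docs = [list(toks) for toks in train_token_sequences]
    if not docs:
        raise ValueError("cannot fit document embeddings on an empty training set")
    counts = Counter(t for doc in docs for t in doc)
    vocab = {w: i for i, w in enumerate(sorted(w for w, c in counts.items() if c >= min_count))}
    if not vocab:
        raise ValueError("no vocabulary after min_count filtering")
    rng = np.random.default_rng(seed)
    v = len(vocab)
    word_in = (rng.random((v, dim)) - 0.5) / dim
    word_out = np.zeros((v, dim))
    doc_vecs = (rng.random((len(docs), dim)) - 0.5) / dim
    freqs = np.array([counts[w] for w in vocab], dtype=float) ** 0.75
    noise_cdf = np.cumsum(freqs / freqs.sum())
    indexed = [[vocab[t] for t in doc if t in vocab] for doc in docs]
    alpha, min_alpha = 0.025, 1e-4
    for epoch in range(epochs):
        lr = alpha - (alpha - min_alpha) * epoch / max(epochs, 1)
        for d, tokens in enumerate(indexed):
            _train_doc(
                tokens, doc_vecs[d], word_in, word_out, noise_cdf, rng,
                window, negative, lr, update_words=True,
            )
    return DocEmbeddingModel(
        dim=dim, min_count=min_count, epochs=epochs, window=window,
        negative=negative, seed=seed, vocab=vocab, word_vectors=word_in,
        output_weights=word_out, doc_vectors=doc_vecs, noise_cdf=noise_cdf,
        alpha=alpha, min_alpha=min_alpha,
    )


def infer_vector(
    model: DocEmbeddingModel,
    tokens: Iterable[str],
    epochs: int | None = None,
    seed: int | None = None,
) -> np.ndarray:
    """Infer a vector for a new document with frozen word/output weights."""
    epochs = model.epochs if epochs is None else epochs
    rng = np.random.default_rng(model.seed if seed is None else seed)
    vec = (rng.random(model.dim) - 0.5) / model.dim
    indexed = [model.vocab[t] for t in tokens if t in model.vocab]
    for epoch in range(epochs):
        lr = model.alpha - (model.alpha - model.min_alpha) * epoch / max(epochs, 1)
        _train_doc(
            indexed, vec, model.word_vectors, model.output_weights,
            model.noise_cdf, rng, model.window, model.negative, lr,
            update_words=False, update_outputs=False,
        )
    return vec
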