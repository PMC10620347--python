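"""Model-ready feature vectors: base representation plus hand-crafted blocks.

A document vector is the concatenation ``[base | pos | dep | pmi | concept]``
where the base block is TF-IDF or a paragraph-vector embedding and the other
blocks are the hand-engineered features (syntactic tag counts, per-class
PMI likely-word-set counts, concept-lexicon features). Blocks are present iff
enabled in the configuration; the segment layout is identical for every
document under one fitted pipeline. All fitting happens on training data
only.

Concept features re-encode the names of the concepts assigned to a document
(by trigger-keyword matching against the synthetic concept lexicon) with the
active base representation fitted on the concept-name vocabulary.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Hashable, Iterable, Sequence

import numpy as np

from . import doc2vec, tfidf
from .lexicon import ConceptLexicon, default_concept_lexicon
from .pmi import PmiLexicon, build_likely_word_sets, likely_set_features
from .taggers import (
    PTB_TAGS,
    UD_RELATIONS,
    Tagger,
    dep_features,
    pos_features,
    rule_dep_tagger,
    rule_pos_tagger,
)

_WORD_RE = re.compile(r"[a-z]+")


def tokenize_concept_name(name: str) -> list[str]:
    return _WORD_RE.findall(name.lower())


def assign_concepts(tokens: Iterable[str], lexicon: ConceptLexicon) -> list[str]:
    """Concepts whose trigger keywords match any token; lexicon order, deduplicated."""
    token_set = set(tokens)
    return [
        entry.concept
        for entry in lexicon
        if any(trigger in token_set for trigger in entry.triggers)
    ]


def concept_features(concepts: Sequence[str], base_model) -> np.ndarray:
    """Encode assigned concept names with the active base representation.

    ``base_model`` is a :class:`~carestrat.tfidf.TfidfModel` or
    :class:`~carestrat.doc2vec.DocEmbeddingModel` fitted on the concept-name
    vocabulary. An empty concept list yields a zero vector.
    """
    names = list(dict.fromkeys(concepts))  # dedup, keep order
    if not names:
        return np.zeros(base_model.dim)
    toks = [t for name in names for t in tokenize_concept_name(name)]
    if isinstance(base_model, tfidf.TfidfModel):
        return tfidf.transform(base_model, toks)
    return doc2vec.infer_vector(base_model, toks)


@dataclass(frozen=True)
class FeatureConfig:
    """Which blocks to build and their hyperparameters."""

    base: str = "tfidf"  # "tfidf" | "doc2vec"
    max_terms: int = 5000
    dim: int = 100
    epochs: int = 30
    min_count: int = 1
    window: int = 5
    use_pos: bool = False
    use_dep: bool = False
    use_pmi: bool = False
    use_concepts: bool = False
    pmi_k: int = 20
    pmi_alpha: float = 0.5
    pmi_min_count: int = 2
    pmi_mode: str = "counts"  # or "indicator"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.base not in ("tfidf", "doc2vec"):
            raise ValueError(f"unknown base representation: {self.base!r}")
        if self.pmi_mode not in ("counts", "indicator"):
            raise ValueError(f"unknown pmi_mode: {self.pmi_mode!r}")

    @property
    def enabled_blocks(self) -> tuple[str, ...]:
        blocks = ["base"]
        if self.use_pos:
            blocks.append("pos")
        if self.use_dep:
            blocks.append("dep")
        if self.use_pmi:
            blocks.append("pmi")
        if self.use_concepts:
            blocks.append("concept")
        return tuple(blocks)


@dataclass(frozen=True)
class FeatureVector:
    """Dense vector with a named-segment map over its blocks."""

    values: np.ndarray
    segments: dict[str, tuple[int, int]]

    def segment(self, name: str) -> np.ndarray:
        start, stop = self.segments[name]
        return self.values[start:stop]


class FeaturePipeline:
    """Fits all configured representations on training data and vectorizes documents."""

    def __init__(
        self,
        config: FeatureConfig,
        lexicon: ConceptLexicon | None = None,
        pos_tagger: Tagger = rule_pos_tagger,
        dep_parser: Tagger = rule_dep_tagger,
    ):
        self.config = config
        self.lexicon = lexicon
        self.pos_tagger = pos_tagger
        self.dep_parser = dep_parser
        self.base_model = None
        self.pmi_lexicon: PmiLexicon | None = None
        self.concept_encoder = None
        self._fitted = False

    def fit(
        self,
        train_token_sequences: Sequence[Iterable[str]],
        labels: Sequence[Hashable] | None = None,
    ) -> "FeaturePipeline":
        docs = [list(t) for t in train_token_sequences]
        cfg = self.config
        if cfg.base == "tfidf":
            self.base_model = tfidf.fit_tfidf(docs, max_terms=cfg.max_terms)
        else:
            self.base_model = doc2vec.fit_doc_embeddings(
                docs, dim=cfg.dim, min_count=cfg.min_count, epochs=cfg.epochs,
                seed=cfg.seed, window=cfg.window,
            )
        if cfg.use_pmi:
            if labels is None:
                raise ValueError("PMI likely word sets require training labels")
            self.pmi_lexicon = build_likely_word_sets(
                docs, list(labels), k=cfg.pmi_k,
                min_count=cfg.pmi_min_count, alpha=cfg.pmi_alpha,
            )
        if cfg.use_concepts:
            if self.lexicon is None:
                self.lexicon = default_concept_lexicon()
            concept_docs = [tokenize_concept_name(e.concept) for e in self.lexicon]
            if cfg.base == "tfidf":
                self.concept_encoder = tfidf.fit_tfidf(concept_docs, max_terms=cfg.max_terms)
            else:
                self.concept_encoder = doc2vec.fit_doc_embeddings(
                    concept_docs, dim=cfg.dim, min_count=cfg.min_count,
                    epochs=cfg.epochs, seed=cfg.seed, window=cfg.window,
                )
        self._fitted = True
        return self

    # -- layout ------------------------------------------------------------
    def _block_length(self, name: str) -> int:
        if name == "base":
            return self.base_model.dim
        if name == "pos":
            return len(PTB_TAGS)
        if name == "dep":
            return len(UD_RELATIONS)
        if name == "pmi":
            return len(self.pmi_lexicon.word_sets)
        if name == "concept":
            return self.concept_encoder.dim
        raise KeyError(name)

    @property
    def segments(self) -> dict[str, tuple[int, int]]:
        self._check_fitted()
        layout: dict[str, tuple[int, int]] = {}
        offset = 0
        for name in self.config.enabled_blocks:
            length = self._block_length(name)
            layout[name] = (offset, offset + length)
            offset += length
        return layout

    @property
    def dim(self) -> int:
        return sum(stop - start for start, stop in self.segments.values())

    def _check_fitted(self) -> None:
        if not self._fitted:
            raise RuntimeError("FeaturePipeline is not fitted")
        for name in self.config.enabled_blocks:
            model = {
                "base": self.base_model,
                "pos": self.pos_tagger,
                "dep": self.dep_parser,
                "pmi": self.pmi_lexicon,
                "concept": self.concept_encoder,
            }[name]
            if model is None:
                raise ValueError(f"feature block {name!r} enabled but its model is absent")

    # -- encoding ----------------------------------------------------------
    def _base_vector(self, tokens: list[str]) -> np.ndarray:
        if self.config.base == "tfidf":
            return tfidf.transform(self.base_model, tokens)
        return doc2vec.infer_vector(self.base_model, tokens)

    def transform_one(self, tokens: Iterable[str]) -> FeatureVector:
        self._check_fitted()
        toks = list(tokens)
        parts: list[np.ndarray] = []
        for name in self.config.enabled_blocks:
            if name == "base":
                parts.append(self._base_vector(toks))
            elif name == "pos":
                parts.append(pos_features(toks, self.pos_tagger))
            elif name == "dep":
                parts.append(dep_features(toks, self.dep_parser))
            elif name == "pmi":
                vec = likely_set_features(toks, self.pmi_lexicon)
                if self.config.pmi_mode == "indicator":
                    vec = (vec > 0).astype(float)
                parts.append(vec)
            elif name == "concept":
                concepts = assign_concepts(toks, self.lexicon)
                parts.append(concept_features(concepts, self.concept_encoder))
        return FeatureVector(values=np.concatenate(parts), segments=self.segments)

    def transform(self, token_sequences: Sequence[Iterable[str]]) -> np.ndarray:
        rows = [self.transform_one(toks).values for toks in token_sequences]
        return np.stack(rows) if rows else np.zeros((0, self.dim))


def build_feature_vector(tokens: Iterable[str], pipeline: FeaturePipeline) -> FeatureVector:
    """Concatenated ``[base | pos | dep | pmi | concept]`` vector for one document."""
    return pipeline.transform_one(tokens)
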