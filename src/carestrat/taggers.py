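"""Syntactic count features: Penn Treebank POS tags, universal dependency relations.

Feature vectors are counts over the two fixed tagsets, so their length never
varies across documents. Taggers are pluggable callables
``tokens -> list[tag]``; the bundled defaults are deterministic rule-based
taggers (closed-class lexicon + suffix rules for POS; a shallow head
heuristic for dependencies) so no external statistical model is required.
A plugged tagger emitting a tag outside the fixed tagset raises a
``ValueError`` listing the offending tag.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

# Penn Treebank word-level tagset (36 tags).
PTB_TAGS: tuple[str, ...] = (
    "CC", "CD", "DT", "EX", "FW", "IN", "JJ", "JJR", "JJS", "LS", "MD",
    "NN", "NNS", "NNP", "NNPS", "PDT", "POS", "PRP", "PRP$", "RB", "RBR",
    "RBS", "RP", "SYM", "TO", "UH", "VB", "VBD", "VBG", "VBN", "VBP", "VBZ",
    "WDT", "WP", "WP$", "WRB",
)

# Universal Dependencies v2 relation inventory (37 relations).
UD_RELATIONS: tuple[str, ...] = (
    "acl", "advcl", "advmod", "amod", "appos", "aux", "case", "cc", "ccomp",
    "clf", "compound", "conj", "cop", "csubj", "dep", "det", "discourse",
    "dislocated", "expl", "fixed", "flat", "goeswith", "iobj", "list",
    "mark", "nmod", "nsubj", "nummod", "obj", "obl", "orphan", "parataxis",
    "punct", "reparandum", "root", "vocative", "xcomp",
)

Tagger = Callable[[Sequence[str]], list[str]]

_DETERMINERS = {"the", "a", "an", "this", "that", "these", "those", "every"}
_PRONOUNS = {"i", "we", "you", "he", "she", "it", "they", "them", "him", "her", "me", "us"}
_POSS_PRONOUNS = {"my", "our", "your", "his", "its", "their"}
_PREPOSITIONS = {
    "in", "on", "at", "of", "for", "with", "by", "from", "into", "about",
    "during", "before", "after", "under", "over", "between", "through",
    "without",
}
_CONJUNCTIONS = {"and", "or", "but", "nor"}
_MODALS = {"can", "will", "should", "must", "may", "might", "could", "would", "shall"}
_ADVERBS = {"not", "never", "always", "often", "sometimes", "rarely", "together", "now", "very", "too", "also", "maybe", "perhaps", "already", "currently"}
_WH = {"what": "WP", "who": "WP", "whom": "WP", "whose": "WP$", "which": "WDT", "when": "WRB", "where": "WRB", "why": "WRB", "how": "WRB"}

_COMMON_VERBS = {
    "sing", "play", "help", "use", "put", "let", "give", "take", "make",
    "go", "come", "try", "keep", "start", "stop", "finish", "begin", "wait",
    "watch", "look", "see", "hear", "ask", "tell", "say", "show", "bring",
    "find", "work", "rest", "sleep", "wake", "eat", "drink", "wash", "dress",
    "clean", "open", "close", "turn", "move", "stay", "leave", "meet",
    "join", "share", "plan", "prepare", "remember", "forget", "know",
    "think", "feel", "need", "set", "get", "allow", "remind", "check",
    "explain", "discuss", "review", "encourage", "reassure", "relax",
    "breathe", "talk", "listen", "support", "choose", "like", "enjoy",
    "select", "want", "wish", "pick", "vote", "decide", "practice", "teach",
    "repeat", "master", "learn", "train", "coach", "demonstrate", "guide",
    "improve", "love", "run", "walk", "sit", "stand", "read", "write",
    "draw", "skip",
}
_COMMON_ADJECTIVES = {
    "quiet", "visual", "proud", "positive", "calm", "happy", "fine", "okay",
    "unsure", "unknown", "unclear", "empty", "blank", "favorite", "fun",
    "small", "big", "short", "long", "new", "old", "easy", "hard", "simple",
    "clear", "loud", "soft", "warm", "cool", "safe", "ready", "extra",
    "applicable", "involved", "needed", "early", "late",
}


def rule_pos_tagger(tokens: Sequence[str]) -> list[str]:
    """Deterministic lexicon+suffix POS tagger over preprocessed lemmas."""
    tags = []
    for tok in tokens:
        low = tok.lower()
        if tok == "[name]":
            tags.append("NNP")
        elif tok == "[number]" or any(ch.isdigit() for ch in tok):
            tags.append("CD")
        elif not tok.isalpha() and tok not in ("[name]", "[number]"):
            tags.append("SYM")
        elif low in _DETERMINERS:
            tags.append("DT")
        elif low == "to":
            tags.append("TO")
        elif low in _PRONOUNS:
            tags.append("PRP")
        elif low in _POSS_PRONOUNS:
            tags.append("PRP$")
        elif low in _WH:
            tags.append(_WH[low])
        elif low in _MODALS:
            tags.append("MD")
        elif low in _CONJUNCTIONS:
            tags.append("CC")
        elif low in _PREPOSITIONS:
            tags.append("IN")
        elif low in _ADVERBS or low.endswith("ly"):
            tags.append("RB")
        elif low in _COMMON_VERBS:
            tags.append("VB")
        elif low.endswith("ing") and len(low) > 5:
            tags.append("VBG")
        elif low.endswith("ed") and len(low) > 4:
            tags.append("VBN")
        elif low in _COMMON_ADJECTIVES or low.endswith(("ful", "ous", "ive", "able")):
            tags.append("JJ")
        elif low.endswith("s") and not low.endswith("ss") and len(low) > 3:
            tags.append("NNS")
        else:
            tags.append("NN")
    return tags


def rule_dep_tagger(tokens: Sequence[str]) -> list[str]:
    """Shallow dependency-relation labeling driven by the rule POS tags.

    The first verb is the root (else the first token); nominals before the
    root are subjects, after it objects; modifiers map to their canonical
    relations. A coarse stand-in for a parser, sufficient for count features.
    """
    pos = rule_pos_tagger(tokens)
    rels: list[str] = []
    root_idx = next((i for i, t in enumerate(pos) if t.startswith("VB")), None)
    if root_idx is None:
        root_idx = 0 if tokens else -1
    for i, (tok, tag) in enumerate(zip(tokens, pos)):
        if i == root_idx:
            rels.append("root")
        elif tag.startswith("NN") or tag == "PRP":
            rels.append("nsubj" if i < root_idx else "obj")
        elif tag.startswith("VB"):
            rels.append("xcomp")
        elif tag == "JJ":
            rels.append("amod")
        elif tag in ("RB", "RBR", "RBS"):
            rels.append("advmod")
        elif tag == "CD":
            rels.append("nummod")
        elif tag in ("DT", "PDT", "PRP$", "WDT"):
            rels.append("det")
        elif tag in ("IN", "TO"):
            rels.append("case")
        elif tag == "CC":
            rels.append("cc")
        elif tag == "MD":
            rels.append("aux")
        elif tag == "SYM":
            rels.append("punct")
        else:
            rels.append("dep")
    return rels


def _count_vector(tags: Iterable[str], tagset: tuple[str, ...], kind: str) -> np.ndarray:
    index = {t: i for i, t in enumerate(tagset)}
    vec = np.zeros(len(tagset))
    for tag in tags:
        if tag not in index:
            raise ValueError(f"unknown {kind} tag emitted by tagger: {tag!r}")
        vec[index[tag]] += 1
    return vec


def pos_features(tokens: Sequence[str], tagger: Tagger = rule_pos_tagger) -> np.ndarray:
    """Count vector over the fixed Penn Treebank tagset."""
    return _count_vector(tagger(list(tokens)), PTB_TAGS, "POS")


def dep_features(tokens: Sequence[str], parser: Tagger = rule_dep_tagger) -> np.ndarray:
    """Count vector over the fixed universal dependency relation set."""
    return _count_vector(parser(list(tokens)), UD_RELATIONS, "dependency")
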