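"""Deterministic text normalization for caregiver-strategy records.

The pipeline applies, in order: (1) case normalization, (2) dictionary-based
spelling correction bounded by edit distance, (3) replacement of personal
names and numbers with ``[name]``/``[number]`` placeholders, (4) punctuation
removal, (5) stopword removal, and finally lemmatization. Placeholders are
exempt from correction, stopword removal and lemmatization, so the pipeline is
idempotent on its own detokenized output.

Name recognition is pluggable; the bundled recognizer is a gazetteer over the
synthetic generator's name inventory plus a digit rule, standing in for the
manually checked named-entity step used on the real data.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources

import edlib

from .corpus import StrategyRecord
from .vocab import FIRST_NAMES

NAME_PLACEHOLDER = "[name]"
NUMBER_PLACEHOLDER = "[number]"
_PLACEHOLDERS = frozenset({NAME_PLACEHOLDER, NUMBER_PLACEHOLDER})

_TOKEN_RE = re.compile(
    r"\[name\]|\[number\]|[a-z]+(?:'[a-z]+)?|[0-9][a-z0-9]*|[^\sa-z0-9]+"
)


def _read_data(name: str) -> str:
    return resources.files("carestrat.data").joinpath(name).read_text(encoding="utf-8")


@lru_cache(maxsize=1)
def default_stopwords() -> frozenset[str]:
    """The bundled fixed 127-word English stopword list."""
    return frozenset(_read_data("stopwords.txt").split())


@lru_cache(maxsize=1)
def default_dictionary() -> frozenset[str]:
    """The bundled small English wordlist used for spelling and lemmas."""
    return frozenset(_read_data("wordlist.txt").split())


@lru_cache(maxsize=1)
def irregular_lemmas() -> dict[str, str]:
    table = {}
    for line in _read_data("irregular_lemmas.tsv").splitlines():
        if line.strip():
            form, lemma = line.split("\t")
            table[form] = lemma
    return table


@dataclass(frozen=True)
class PreprocessConfig:
    """Knobs of the normalization pipeline.

    ``dictionary`` is the set of words considered correctly spelled; callers
    typically extend the bundled wordlist with the training-corpus vocabulary
    (see :func:`dictionary_from_corpus`). ``token_frequencies`` breaks
    spelling-correction ties toward more frequent training words.
    """

    max_edit_distance: int = 2
    name_placeholder: str = NAME_PLACEHOLDER
    number_placeholder: str = NUMBER_PLACEHOLDER
    stopword_list: frozenset[str] = field(default_factory=default_stopwords)
    dictionary: frozenset[str] = field(default_factory=default_dictionary)
    names: frozenset[str] = frozenset(n.lower() for n in FIRST_NAMES)
    token_frequencies: dict[str, int] | None = None
    _spell_cache: dict[str, str] = field(
        default_factory=dict, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        if self.max_edit_distance < 0:
            raise ValueError("max_edit_distance must be >= 0")
        if not self.name_placeholder or not self.number_placeholder:
            raise ValueError("placeholders must be non-empty")


@dataclass(frozen=True)
class TokenSequence:
    """Ordered lowercase lemmas; ``empty`` flags documents normalized away."""

    tokens: tuple[str, ...]

    @property
    def empty(self) -> bool:
        return len(self.tokens) == 0

    def __iter__(self):
        return iter(self.tokens)

    def __len__(self) -> int:
        return len(self.tokens)


def edit_distance(a: str, b: str) -> int:
    """Unit-cost Levenshtein distance (insert/delete/substitute)."""
    if a == b:
        return 0
    if len(a) < len(b):
        a, b = b, a
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, start=1):
        cur = [i]
        for j, cb in enumerate(b, start=1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def _is_word(token: str) -> bool:
    return token.isalpha()


def correct_spelling(token: str, config: PreprocessConfig) -> str:
    """Replace an out-of-dictionary word by its nearest dictionary word.

    Ties break toward smaller distance, then higher training frequency, then
    lexicographic order; words farther than ``max_edit_distance`` from every
    dictionary entry are kept as-is. Placeholders, gazetteer names and
    non-alphabetic tokens are never touched.
    """
    if (
        token in _PLACEHOLDERS
        or not _is_word(token)
        or token in config.dictionary
        or token in config.names
    ):
        return token
    cached = config._spell_cache.get(token)
    if cached is not None:
        return cached
    k = config.max_edit_distance
    freqs = config.token_frequencies or {}
    best: tuple[int, int, str] | None = None
    for word in config.dictionary:
        if abs(len(word) - len(token)) > k:
            continue
        d = edlib.align(token, word, task="distance", k=k)["editDistance"]
        if d < 0:  # beyond the bound
            continue
        key = (d, -freqs.get(word, 0), word)
        if best is None or key < best:
            best = key
    result = best[2] if best is not None else token
    config._spell_cache[token] = result
    return result


def _replace_entity_token(token: str, config: PreprocessConfig) -> str:
    if token in config.names:
        return config.name_placeholder
    if any(ch.isdigit() for ch in token):
        return config.number_placeholder
    return token


def replace_entities(text: str, config: PreprocessConfig | None = None) -> str:
    """Replace personal names and digit-bearing tokens with placeholders.

    Operates on whitespace tokens of raw text, preserving attached
    punctuation (``"Anna!"`` becomes ``"[name]!"``).
    """
    config = config or PreprocessConfig()
    out = []
    for raw in text.split():
        m = re.match(r"([^\w]*)([\w']+)([^\w]*)$", raw)
        if m is None:
            out.append(raw)
            continue
        prefix, core, suffix = m.groups()
        replaced = _replace_entity_token(core.lower(), config)
        out.append(raw if replaced == core.lower() else prefix + replaced + suffix)
    return " ".join(out)


def lemmatize(token: str, dictionary: frozenset[str] | None = None) -> str:
    """Map a lowercase token to its lemma.

    Irregular forms go through the bundled exception table; regular
    inflections (-s/-es, -ing, -ed) are stripped with e-restoration and
    consonant-undoubling, consulting ``dictionary`` (default: bundled
    wordlist) to decide between candidate stems. Placeholders and
    non-alphabetic tokens pass through.
    """
    if token in _PLACEHOLDERS or not _is_word(token):
        return token
    table = irregular_lemmas()
    if token in table:
        return table[token]
    dictionary = dictionary if dictionary is not None else default_dictionary()

    def _resolve(stem: str) -> str | None:
        # only dictionary-confirmed stems: stripping must never invent words
        if len(stem) < 2:
            return None
        if stem + "e" in dictionary:
            return stem + "e"
        if stem in dictionary:
            return stem
        if len(stem) >= 3 and stem[-1] == stem[-2] and stem[:-1] in dictionary:
            return stem[:-1]
        return None

    # plural
    if token.endswith("ies") and len(token) > 4:
        token = token[:-3] + "y"
    elif token.endswith(("ches", "shes", "sses", "xes", "zes")) and len(token) > 4:
        token = token[:-2]
    elif token.endswith("s") and not token.endswith(("ss", "us", "is")) and len(token) > 3:
        token = token[:-1]
    if token in table:
        return table[token]
    # progressive
    if token.endswith("ing") and len(token) > 5:
        out = _resolve(token[:-3])
        if out is not None:
            return out
    # past tense (skip -eed words: need, speed, agreed)
    if token.endswith("ed") and not token.endswith("eed") and len(token) >= 4:
        out = _resolve(token[:-2])
        if out is not None:
            return out
    return token


def tokenize(text: str) -> list[str]:
    """Lowercase and split into word / number / punctuation / placeholder tokens."""
    return _TOKEN_RE.findall(text.lower())


def preprocess(
    record: StrategyRecord | str, config: PreprocessConfig | None = None
) -> TokenSequence:
    """Run the full normalization pipeline on one record (or raw string).

    May return an empty sequence (flagged via :attr:`TokenSequence.empty`),
    e.g. when every token was a stopword; empty outputs are retained so
    record counts reconcile downstream.
    """
    config = config or PreprocessConfig()
    text = record.text if isinstance(record, StrategyRecord) else record
    tokens = tokenize(text)  # (1) case normalization happens inside tokenize
    tokens = [correct_spelling(t, config) for t in tokens]  # (2)
    tokens = [_replace_entity_token(t, config) for t in tokens]  # (3)
    tokens = [t for t in tokens if t in _PLACEHOLDERS or not _is_punct(t)]  # (4)
    tokens = [t for t in tokens if t in _PLACEHOLDERS or t not in config.stopword_list]
    lemmas = tuple(lemmatize(t, config.dictionary) for t in tokens)
    return TokenSequence(lemmas)


def _is_punct(token: str) -> bool:
    return not any(ch.isalnum() for ch in token)


def dictionary_from_corpus(
    texts: list[str], min_frequency: int = 2
) -> tuple[frozenset[str], dict[str, int]]:
    """Extend the bundled dictionary with recurring training-corpus words.

    Words seen fewer than ``min_frequency`` times are excluded (one-off
    misspellings should not become valid spellings). Returns the merged
    dictionary and the raw token frequencies for tie-breaking.
    """
    freqs: dict[str, int] = {}
    for text in texts:
        for tok in tokenize(text):
            if _is_word(tok):
                freqs[tok] = freqs.get(tok, 0) + 1
    recurring = {w for w, c in freqs.items() if c >= min_frequency}
    return default_dictionary() | recurring, freqs


def preprocess_corpus(
    records: list[StrategyRecord], config: PreprocessConfig
) -> list[TokenSequence]:
    return [preprocess(rec, config) for rec in records]
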