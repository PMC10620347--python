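"""Word inventories for the synthetic caregiver-strategy language.

The generator composes utterances from three lexical strata:

* per-class keyword pools — content words whose frequency is biased toward one
  strategy class (these carry the learnable signal);
* a shared vocabulary — class-neutral content words, a core of common English
  filler words padded with deterministically generated pronounceable
  pseudo-words up to the configured vocabulary size;
* function words (a small stopword subset), personal names and digit strings
  injected as surface noise.

All keyword pools hold lemma-form lowercase words so they survive the
preprocessing pipeline unchanged.
"""

from __future__ import annotations

import numpy as np

from .labels import ClassLabel

# ---------------------------------------------------------------------------
# Class keyword pools (40 words each, pairwise disjoint).

ENV_KEYWORDS: tuple[str, ...] = (
    "quiet", "room", "space", "schedule", "routine", "timer", "music",
    "headphone", "picture", "chart", "calendar", "light", "noise", "corner",
    "desk", "seat", "ramp", "rail", "door", "furniture", "visual", "cue",
    "reminder", "checklist", "label", "area", "home", "classroom",
    "playground", "environment", "structure", "arrangement", "distraction",
    "barrier", "access", "equipment", "tool", "layout", "neighbor",
    "transport",
)

SELF_KEYWORDS: tuple[str, ...] = (
    "confidence", "praise", "encourage", "proud", "esteem", "belief",
    "identity", "motivation", "emotion", "calm", "comfort", "reassure",
    "affirmation", "strength", "worth", "pride", "courage", "positive",
    "mindset", "resilience", "feel", "mood", "anxiety", "stress", "relax",
    "breathe", "patience", "trust", "independence", "ownership",
    "responsibility", "maturity", "awareness", "reflection", "journal",
    "talk", "listen", "support", "empathy", "kindness",
)

PREF_KEYWORDS: tuple[str, ...] = (
    "choice", "choose", "favorite", "interest", "preference", "like", "enjoy",
    "fun", "hobby", "passion", "option", "select", "want", "wish", "desire",
    "pick", "theme", "game", "toy", "sport", "art", "craft", "dance", "song",
    "animal", "color", "food", "snack", "reward", "motivator", "topic",
    "character", "style", "activity", "variety", "menu", "vote", "decide",
    "opinion", "taste",
)

COMP_KEYWORDS: tuple[str, ...] = (
    "practice", "skill", "teach", "step", "instruction", "repeat", "drill",
    "master", "learn", "train", "coach", "demonstrate", "model", "guide",
    "task", "goal", "progress", "level", "challenge", "improve", "ability",
    "competence", "technique", "exercise", "lesson", "tutor", "homework",
    "breakdown", "sequence", "attempt", "effort", "feedback", "correction",
    "milestone", "speed", "accuracy", "endurance", "coordination", "balance",
    "memory",
)

NONSTRAT_KEYWORDS: tuple[str, ...] = (
    "none", "nothing", "nobody", "never", "unsure", "unknown", "unclear",
    "question", "blank", "skip", "empty", "already", "fine", "okay", "happy",
    "involved", "needed", "applicable", "answer", "comment", "response",
    "idea", "moment", "time", "currently", "situation", "issue", "problem",
    "difficulty", "help", "maybe", "perhaps", "sometimes", "rarely", "nope",
    "na", "without", "beyond", "else", "anything",
)

CLASS_KEYWORDS: dict[ClassLabel, tuple[str, ...]] = {
    ClassLabel.ENV: ENV_KEYWORDS,
    ClassLabel.SELF: SELF_KEYWORDS,
    ClassLabel.PREF: PREF_KEYWORDS,
    ClassLabel.COMP: COMP_KEYWORDS,
    ClassLabel.NONSTRAT: NONSTRAT_KEYWORDS,
}

# ---------------------------------------------------------------------------
# Fixed one-word-or-short refusal templates for the non-strategy class.

REFUSAL_TEMPLATES: tuple[str, ...] = (
    "none",
    "nothing",
    "no strategies needed",
    "none needed",
)

# ---------------------------------------------------------------------------
# Personal-name inventory; doubles as the entity-replacement gazetteer.

FIRST_NAMES: tuple[str, ...] = (
    "Anna", "Ben", "Clara", "David", "Emma", "Felix", "Grace", "Henry",
    "Isla", "Jacob", "Kara", "Liam", "Mia", "Noah", "Olivia", "Peter",
    "Quinn", "Rosa", "Sam", "Tessa", "Umar", "Vera", "Will", "Ximena",
    "Yusuf", "Zoe", "Aiden", "Bella", "Carlos", "Diana", "Ethan", "Fiona",
    "Gavin", "Hana", "Ivan", "Julia", "Kevin", "Lena", "Marco", "Nina",
)

# ---------------------------------------------------------------------------
# Class-neutral real filler words (all common English, lemma form).

FILLER_WORDS: tuple[str, ...] = (
    "child", "school", "day", "week", "morning", "evening", "night",
    "dinner", "breakfast", "family", "parent", "teacher", "friend", "sister",
    "brother", "group", "team", "club", "visit", "trip", "park", "store",
    "church", "bus", "car", "walk", "run", "sit", "stand", "read", "write",
    "draw", "book", "page", "story", "word", "movie", "show", "phone",
    "computer", "tablet", "video", "try", "keep", "start", "stop", "finish",
    "begin", "wait", "watch", "look", "see", "hear", "ask", "tell", "say",
    "show", "give", "take", "bring", "find", "make", "work", "rest", "sleep",
    "wake", "eat", "drink", "wash", "dress", "clean", "open", "close",
    "turn", "move", "stay", "leave", "come", "go", "meet", "join", "share",
    "plan", "prepare", "remember", "forget", "know", "think", "feel", "need",
    "use", "set", "put", "get", "let", "allow", "remind", "check", "explain",
    "discuss", "review", "together", "slowly", "quickly", "early", "late",
    "often", "daily", "weekly", "extra", "small", "big", "short", "long",
    "new", "old", "easy", "hard", "simple", "clear", "loud", "soft", "warm",
    "cool", "safe", "ready", "person", "people", "place", "thing", "way",
    "year", "month", "hour", "minute", "house", "yard", "table", "chair",
    "floor", "wall", "window", "box", "bag", "list", "note", "card", "sign",
    "drum", "piano", "ball", "bike", "pool", "water", "garden", "dog", "cat",
    "play", "sing", "help", "love", "enjoyment",
)

# First tokens of an utterance, to give records a sentence-ish shape.
OPENERS: tuple[str, ...] = (
    "we", "i", "she", "he", "they", "our", "my", "his", "her", "the",
)


def make_pseudo_word(rng: np.random.Generator) -> str:
    """One pronounceable CV-syllable pseudo-word (2-4 syllables)."""
    onsets = "bcdfglmnprstvz"
    vowels = "aeiou"
    n_syll = int(rng.integers(2, 5))
    return "".join(
        onsets[int(rng.integers(len(onsets)))] + vowels[int(rng.integers(len(vowels)))]
        for _ in range(n_syll)
    )


_SHARED_VOCAB_SEED = 20230918  # fixed: the shared vocabulary is a property of
# the synthetic language, not of any one sampled corpus


def shared_vocabulary(size: int) -> tuple[str, ...]:
    """Class-neutral content vocabulary of exactly ``size`` types.

    Real filler words first, then deterministic pseudo-words; never overlaps
    the class keyword pools.
    """
    if size < 0:
        raise ValueError("shared vocabulary size must be >= 0")
    reserved = {w for pool in CLASS_KEYWORDS.values() for w in pool}
    words: list[str] = []
    seen: set[str] = set()
    for w in FILLER_WORDS:
        if w not in reserved and w not in seen:
            words.append(w)
            seen.add(w)
        if len(words) >= size:
            return tuple(words[:size])
    rng = np.random.default_rng(_SHARED_VOCAB_SEED)
    while len(words) < size:
        w = make_pseudo_word(rng)
        if w in reserved or w in seen:
            continue
        words.append(w)
        seen.add(w)
    return tuple(words)
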