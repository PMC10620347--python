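"""Concept lexicon emulating a manual UMLS concept mapping.

The study clustered its strategies into 71 concepts (38 environment/context,
15 sense of self, 12 preferences, 6 activity competence), of which 49 mapped
to existing UMLS concepts. The real mapping table is not distributed with the
paper, so the default lexicon here is a synthetic stand-in
(``data/synthetic_concept_lexicon.tsv``) with the same shape: each concept
carries trigger keywords drawn from the corresponding generator keyword pool,
a mapped/unmapped flag (49 mapped, with the per-class unmapped split 12/6/3/1)
and, for mapped concepts, a source-vocabulary tag.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator

from .labels import ClassLabel, parse_label

_HEADER = ["concept", "label", "triggers", "umls_mapped", "source_vocabulary"]


@dataclass(frozen=True)
class ConceptEntry:
    """One concept: name, strategy class, trigger keywords, mapping metadata."""

    concept: str
    label: ClassLabel
    triggers: tuple[str, ...]
    umls_mapped: bool
    source_vocabulary: str | None = None

    def __post_init__(self) -> None:
        if self.label is ClassLabel.NONSTRAT:
            raise ValueError("concepts describe strategies; NONSTRAT not allowed")
        if not self.triggers:
            raise ValueError(f"concept {self.concept!r} has no trigger keywords")


class ConceptLexicon:
    """Ordered collection of :class:`ConceptEntry`."""

    def __init__(self, entries: Iterable[ConceptEntry]):
        self.entries: tuple[ConceptEntry, ...] = tuple(entries)
        names = [e.concept for e in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("duplicate concept names in lexicon")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[ConceptEntry]:
        return iter(self.entries)

    def count_by_label(self) -> dict[ClassLabel, int]:
        counts: dict[ClassLabel, int] = {}
        for e in self.entries:
            counts[e.label] = counts.get(e.label, 0) + 1
        return counts

    @property
    def n_mapped(self) -> int:
        return sum(e.umls_mapped for e in self.entries)


def _parse_lines(lines: Iterable[str], origin: str) -> ConceptLexicon:
    it = iter(lines)
    header = next(it).rstrip("\n").split("\t")
    if header != _HEADER:
        raise ValueError(f"{origin}: unexpected lexicon header {header!r}")
    entries = []
    for lineno, line in enumerate(it, start=2):
        line = line.rstrip("\n")
        if not line:
            continue
        parts = line.split("\t")
        if len(parts) != 5:
            raise ValueError(f"{origin}:{lineno}: expected 5 fields, got {len(parts)}")
        concept, label, triggers, mapped, source = parts
        entries.append(
            ConceptEntry(
                concept=concept,
                label=parse_label(label),
                triggers=tuple(t for t in triggers.split(",") if t),
                umls_mapped={"true": True, "false": False}[mapped],
                source_vocabulary=source or None,
            )
        )
    return ConceptLexicon(entries)


def read_lexicon(path: str | Path) -> ConceptLexicon:
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        return _parse_lines(fh, str(path))


def write_lexicon(lexicon: ConceptLexicon, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("\t".join(_HEADER) + "\n")
        for e in lexicon:
            fh.write(
                f"{e.concept}\t{e.label.value}\t{','.join(e.triggers)}\t"
                f"{str(e.umls_mapped).lower()}\t{e.source_vocabulary or ''}\n"
            )


def default_concept_lexicon() -> ConceptLexicon:
    """The bundled synthetic 71-concept lexicon (38/15/12/6, 49 mapped)."""
    text = (
        resources.files("carestrat.data")
        .joinpath("synthetic_concept_lexicon.tsv")
        .read_text(encoding="utf-8")
    )
    return _parse_lines(text.splitlines(), "synthetic_concept_lexicon.tsv")
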