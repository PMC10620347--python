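"""Corpus container and tab-separated on-disk format.

A corpus is a list of :class:`StrategyRecord`; on disk it is UTF-8 TSV with a
``id<TAB>text<TAB>label`` header, one record per line.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .labels import ClassLabel, parse_label


@dataclass(frozen=True)
class StrategyRecord:
    """One caregiver utterance with its five-way gold label."""

    id: str
    text: str
    label: ClassLabel

    def __post_init__(self) -> None:
        if not self.text:
            raise ValueError(f"record {self.id!r} has empty text")


Corpus = list[StrategyRecord]


def validate_corpus(records: Sequence[StrategyRecord]) -> None:
    """Check id uniqueness and non-empty texts."""
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"duplicate record id: {rec.id!r}")
        seen.add(rec.id)


def write_corpus(records: Iterable[StrategyRecord], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("id\ttext\tlabel\n")
        for rec in records:
            if "\t" in rec.text or "\n" in rec.text:
                raise ValueError(f"record {rec.id!r}: text contains TSV delimiters")
            fh.write(f"{rec.id}\t{rec.text}\t{rec.label.value}\n")


def read_corpus(path: str | Path) -> Corpus:
    path = Path(path)
    records: Corpus = []
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
        if header.split("\t") != ["id", "text", "label"]:
            raise ValueError(f"unexpected corpus header: {header!r}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 fields, got {len(parts)}")
            rec_id, text, label = parts
            records.append(StrategyRecord(rec_id, text, parse_label(label)))
    validate_corpus(records)
    return records
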