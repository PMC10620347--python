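"""Five-way label scheme for participation-focused caregiver strategies.

Four classes are participation-related constructs — the extrinsic
environment/context class and the three intrinsic classes (sense of self,
preferences, activity competence) — plus a non-strategy class for caregiver
entries that do not describe a strategy (e.g. "none").
"""

from __future__ import annotations

from enum import Enum


class ClassLabel(str, Enum):
    """Gold label of a caregiver-strategy record."""

    ENV = "ENV"  # environment/context (extrinsic)
    SELF = "SELF"  # sense of self (intrinsic)
    PREF = "PREF"  # preferences (intrinsic)
    COMP = "COMP"  # activity competence (intrinsic)
    NONSTRAT = "NONSTRAT"  # not a strategy

    def __str__(self) -> str:  # serialize as the bare value
        return self.value


#: Classes that describe an actual strategy (everything but NONSTRAT).
STRATEGY_CLASSES: tuple[ClassLabel, ...] = (
    ClassLabel.ENV,
    ClassLabel.SELF,
    ClassLabel.PREF,
    ClassLabel.COMP,
)

#: Intrinsic classes target the child; the extrinsic class targets the context.
INTRINSIC_CLASSES: tuple[ClassLabel, ...] = (
    ClassLabel.SELF,
    ClassLabel.PREF,
    ClassLabel.COMP,
)
EXTRINSIC_CLASSES: tuple[ClassLabel, ...] = (ClassLabel.ENV,)

ALL_CLASSES: tuple[ClassLabel, ...] = tuple(ClassLabel)


def parse_label(value: str) -> ClassLabel:
    """Parse a serialized label, raising ``ValueError`` with the bad value."""
    try:
        return ClassLabel(value)
    except ValueError as exc:
        raise ValueError(f"unknown class label: {value!r}") from exc
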