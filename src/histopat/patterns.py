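"""Tissue classes and slide-level labels.

Non-mucinous lung adenocarcinoma is graded by five WHO growth patterns
(lepidic, acinar, papillary, micropapillary, solid); everything
non-neoplastic (inflammation, scarring, fibrosis, artifacts) is pooled
into a single benign class.  A slide carries one *predominant* cancer
pattern plus a (possibly empty) set of *minor* patterns; benign tissue
never appears in the slide-level label.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import FrozenSet, Iterable, Optional


class PatternClass(enum.IntEnum):
    """The six patch-level tissue classes, in canonical ordinal order."""

    LEPIDIC = 0
    ACINAR = 1
    PAPILLARY = 2
    MICROPAPILLARY = 3
    SOLID = 4
    BENIGN = 5

    @property
    def is_cancer(self) -> bool:
        return self is not PatternClass.BENIGN

    @property
    def label(self) -> str:
        return self.name.lower()

    @classmethod
    def from_label(cls, label: str) -> "PatternClass":
        try:
            return cls[label.strip().upper()]
        except KeyError:
            raise ValueError(f"unknown pattern class {label!r}") from None


#: The five cancer patterns in canonical order (benign excluded).
CANCER_CLASSES: tuple[PatternClass, ...] = tuple(
    c for c in PatternClass if c.is_cancer
)

ALL_CLASSES: tuple[PatternClass, ...] = tuple(PatternClass)

N_CLASSES = len(ALL_CLASSES)


@dataclass(frozen=True)
class SlideLabel:
    """Slide-level annotation: predominant cancer pattern plus minor patterns.

    ``predominant is None`` is the benign-slide sentinel (no cancer pattern
    survives on the slide).  Benign can never be predominant or minor.
    """

    predominant: Optional[PatternClass]
    minors: FrozenSet[PatternClass] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        minors = frozenset(self.minors)
        object.__setattr__(self, "minors", minors)
        if self.predominant is not None and not self.predominant.is_cancer:
            raise ValueError("benign cannot be the predominant pattern")
        if any(not m.is_cancer for m in minors):
            raise ValueError("benign cannot be a minor pattern")
        if self.predominant is not None and self.predominant in minors:
            raise ValueError("predominant pattern cannot also be minor")
        if self.predominant is None and minors:
            raise ValueError("a benign slide cannot carry minor patterns")

    @property
    def is_benign(self) -> bool:
        return self.predominant is None

    @property
    def patterns(self) -> FrozenSet[PatternClass]:
        """All patterns present (predominant plus minors)."""
        if self.predominant is None:
            return frozenset()
        return self.minors | {self.predominant}

    @property
    def predominant_name(self) -> str:
        return "benign" if self.predominant is None else self.predominant.label

    def to_dict(self) -> dict:
        return {
            "predominant": self.predominant_name,
            "minors": sorted(m.label for m in self.minors),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SlideLabel":
        pred = d["predominant"]
        predominant = None if pred in (None, "benign") else PatternClass.from_label(pred)
        minors = frozenset(PatternClass.from_label(m) for m in d.get("minors", []))
        return cls(predominant, minors)

    @classmethod
    def benign(cls) -> "SlideLabel":
        return cls(None, frozenset())


def jaccard(a: Iterable, b: Iterable) -> float:
    """Jaccard similarity of two sets; two empty sets agree perfectly (1.0)."""
    sa, sb = set(a), set(b)
    if not sa and not sb:
        return 1.0
    return len(sa & sb) / len(sa | sb)
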