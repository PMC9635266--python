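"""Grammatical category codebooks for noun-related and verb-related coding.

Two fixed codebooks ship with the package as versioned YAML: 14 noun-related
categories (10 syntactic + 4 bound-morphological) and 16 verb-related
categories (5 syntactic + 11 bound-morphological).  Verb coding deliberately
omits noun-phrase structures, so it is "verb-related" rather than a full verb
phrase.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterator

import yaml

__all__ = [
    "GramCategory",
    "Codebook",
    "noun_codebook",
    "verb_codebook",
    "default_codebooks",
]

TYPES = ("noun", "verb")
LEVELS = ("lexical", "grammar")
SUBLEVELS = ("syntax", "morphology")


@dataclass(frozen=True)
class GramCategory:
    """One grammatical category: a label, its class, sub-level, and code."""

    label: str
    type: str  # "noun" | "verb"
    sublevel: str  # "syntax" | "morphology"
    code: int

    def __post_init__(self) -> None:
        if self.type not in TYPES:
            raise ValueError(f"unknown category type {self.type!r}")
        if self.sublevel not in SUBLEVELS:
            raise ValueError(f"unknown sublevel {self.sublevel!r}")
        if self.code <= 0:
            raise ValueError("category code must be a positive integer")


class Codebook:
    """Bijective label <-> code mapping for one category type."""

    def __init__(self, type: str, categories: list[GramCategory]):
        if type not in TYPES:
            raise ValueError(f"unknown codebook type {type!r}")
        labels = [c.label for c in categories]
        codes = [c.code for c in categories]
        if len(set(labels)) != len(labels) or len(set(codes)) != len(codes):
            raise ValueError("codebook labels/codes must be a bijection")
        if any(c.type != type for c in categories):
            raise ValueError("category type mismatch within codebook")
        self.type = type
        self._by_label = {c.label: c for c in categories}
        self._by_code = {c.code: c for c in categories}

    def __len__(self) -> int:
        return len(self._by_label)

    def __contains__(self, label: str) -> bool:
        return label in self._by_label

    def __iter__(self) -> Iterator[GramCategory]:
        return iter(self._by_label.values())

    def __getitem__(self, label: str) -> GramCategory:
        return self._by_label[label]

    @property
    def labels(self) -> list[str]:
        return list(self._by_label)

    def code(self, label: str) -> int:
        return self._by_label[label].code

    def label(self, code: int) -> str:
        return self._by_code[code].label

    def is_morphology(self, label: str) -> bool:
        return self._by_label[label].sublevel == "morphology"


def _load(resource: str, type: str) -> Codebook:
    text = resources.files("recurlang.data").joinpath(resource).read_text()
    raw = yaml.safe_load(text)
    cats = [
        GramCategory(label=c["label"], type=raw["type"],
                     sublevel=c["sublevel"], code=int(c["code"]))
        for c in raw["categories"]
    ]
    return Codebook(type, cats)


def noun_codebook() -> Codebook:
    """The 14-category noun-related codebook."""
    return _load("noun_categories.yaml", "noun")


def verb_codebook() -> Codebook:
    """The 16-category verb-related codebook."""
    return _load("verb_categories.yaml", "verb")


def default_codebooks() -> dict[str, Codebook]:
    """Both shipped codebooks keyed by type."""
    return {"noun": noun_codebook(), "verb": verb_codebook()}
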