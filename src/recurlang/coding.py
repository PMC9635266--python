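"""Coding transcripts into the four integer series used for recurrence.

For each child we build four symbol series — (noun, verb) x (lexical,
grammar).  Positive symbols identify the target material: at the *lexical*
level each token whose unit list for the target type is nonempty contributes
the integer id of its normalized surface form (exact-repetition identity, so
``ice_creams`` is a different word from ``ice_cream``); at the *grammar*
level such a token expands into one symbol per grammatical unit, in annotated
order, carrying the category's codebook code.

Everything outside the target class is masked with a unique, non-repeating
negative id (one per out-of-class token, also at grammar level), so masked
material occupies its time position but can never recur.  Utterances are
concatenated in order with no boundary markers, so deterministic lines may
span utterance boundaries.  Mask ids run -1, -2, ... deterministically, which
changes nothing downstream (recurrence only ever sees positive matches) but
keeps emitted files reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .codebooks import LEVELS, TYPES, Codebook, default_codebooks
from .transcript import Transcript

__all__ = ["CodedSequence", "encode", "encode_all",
           "count_symbol", "count_ngram",
           "write_coded_sequence", "read_coded_sequence"]


@dataclass
class CodedSequence:
    """One integer symbol series for a (child, type, level)."""

    child_id: str
    type: str      # "noun" | "verb"
    level: str     # "lexical" | "grammar"
    symbols: np.ndarray          # int array; >0 target ids, <0 unique masks
    label_map: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.symbols = np.asarray(self.symbols, dtype=np.int64)
        if self.symbols.ndim != 1:
            raise ValueError("symbols must be one-dimensional")

    def __len__(self) -> int:
        return int(self.symbols.size)

    @property
    def n(self) -> int:
        return len(self)

    def positive_labels(self) -> list[str]:
        """In-order labels of the positive (target) symbols."""
        return [self.label_map[int(s)] for s in self.symbols if s > 0]

    def with_symbols(self, symbols: np.ndarray) -> "CodedSequence":
        return CodedSequence(self.child_id, self.type, self.level,
                             symbols, dict(self.label_map))


def encode(t: Transcript, type: str, level: str,
           codebooks: dict[str, Codebook] | None = None) -> CodedSequence:
    """Encode one transcript into the series for (type, level)."""
    if type not in TYPES:
        raise ValueError(f"type must be one of {TYPES}, got {type!r}")
    if level not in LEVELS:
        raise ValueError(f"level must be one of {LEVELS}, got {level!r}")
    codebooks = codebooks or default_codebooks()
    book = codebooks[type]

    symbols: list[int] = []
    label_map: dict[int, str] = {}
    word_ids: dict[str, int] = {}
    next_mask = -1

    for tok in t.tokens:
        units = tok.noun_units if type == "noun" else tok.verb_units
        if not units:
            symbols.append(next_mask)
            next_mask -= 1
            continue
        if level == "lexical":
            wid = word_ids.get(tok.surface)
            if wid is None:
                wid = len(word_ids) + 1
                word_ids[tok.surface] = wid
                label_map[wid] = tok.surface
            symbols.append(wid)
        else:  # grammar: one symbol per unit, in annotated order
            for u in units:
                code = book.code(u)
                label_map.setdefault(code, u)
                symbols.append(code)

    return CodedSequence(child_id=t.child_id, type=type, level=level,
                         symbols=np.array(symbols, dtype=np.int64),
                         label_map=label_map)


def encode_all(t: Transcript,
               codebooks: dict[str, Codebook] | None = None
               ) -> dict[tuple[str, str], CodedSequence]:
    """All four series for one transcript, keyed by (type, level)."""
    codebooks = codebooks or default_codebooks()
    return {(ty, lv): encode(t, ty, lv, codebooks)
            for ty in TYPES for lv in LEVELS}


def count_symbol(s: CodedSequence, label: str) -> int:
    """Number of positions carrying the positive id of `label` (0 if absent)."""
    ids = [i for i, lab in s.label_map.items() if lab == label]
    if not ids:
        return 0
    return int(np.isin(s.symbols, ids).sum())


def count_ngram(s: CodedSequence, labels: list[str]) -> int:
    """Start positions where consecutive positive symbols match `labels`.

    Masked (negative) symbols never match, so an intervening out-of-class
    token breaks the n-gram.
    """
    if not labels:
        raise ValueError("labels must be nonempty")
    inverse = {lab: i for i, lab in s.label_map.items()}
    try:
        target = np.array([inverse[lab] for lab in labels], dtype=np.int64)
    except KeyError:
        return 0
    k, a = len(target), s.symbols
    if a.size < k:
        return 0
    windows = np.lib.stride_tricks.sliding_window_view(a, k)
    return int((windows == target).all(axis=1).sum())


# ---------------------------------------------------------------------------
# series files: whitespace-separated integers plus a JSON sidecar label map

def write_coded_sequence(s: CodedSequence, path) -> None:
    path = Path(path)
    path.write_text(" ".join(str(int(x)) for x in s.symbols) + "\n")
    sidecar = path.with_suffix(path.suffix + ".labels.json")
    meta = {"child_id": s.child_id, "type": s.type, "level": s.level,
            "label_map": {str(k): v for k, v in s.label_map.items()}}
    sidecar.write_text(json.dumps(meta, indent=1, sort_keys=True) + "\n")


def read_coded_sequence(path) -> CodedSequence:
    path = Path(path)
    text = path.read_text().split()
    symbols = np.array([int(x) for x in text], dtype=np.int64)
    meta = json.loads(
        path.with_suffix(path.suffix + ".labels.json").read_text())
    return CodedSequence(
        child_id=meta["child_id"], type=meta["type"], level=meta["level"],
        symbols=symbols,
        label_map={int(k): v for k, v in meta["label_map"].items()})
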