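"""Reading, validating and describing annotated speech transcripts.

A transcript is the ordered child-only side of a play-based language sample:
one row per spoken token, each token carrying the noun-related and
verb-related grammatical units an annotator assigned to it.  The on-disk
dialect is a UTF-8 CSV/TSV with header
``child_id,utterance_index,token_index,surface,noun_units,verb_units``
where unit lists are ``+``-joined category labels (empty allowed).  One file
may hold one child or a pooled cohort.

Surfaces are normalized to lower case; multiword lexical items must arrive
pre-joined with underscores (``ice_cream``) so that exact-repetition identity
is deterministic.  Unintelligible speech is carried as surface ``xxx`` with
empty unit lists: it occupies a time position but can never recur at a target
level, and it is excluded from morpheme and type/token counts.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .codebooks import Codebook, default_codebooks

__all__ = [
    "Token",
    "Utterance",
    "Transcript",
    "SpeechDescriptives",
    "TranscriptError",
    "normalize_surface",
    "read_transcript",
    "read_cohort",
    "write_transcript",
    "write_cohort",
    "speech_descriptives",
    "filter_cohort",
]

COLUMNS = ["child_id", "utterance_index", "token_index",
           "surface", "noun_units", "verb_units"]

UNINTELLIGIBLE = "xxx"


class TranscriptError(ValueError):
    """Malformed transcript file or invalid annotation."""


def normalize_surface(surface: str) -> str:
    """Lower-case and join internal whitespace with underscores."""
    s = str(surface).strip().lower()
    return re.sub(r"\s+", "_", s)


@dataclass(frozen=True)
class Token:
    surface: str
    noun_units: tuple[str, ...] = ()
    verb_units: tuple[str, ...] = ()
    utterance_index: int = 0
    position: int = 0

    @property
    def is_unintelligible(self) -> bool:
        return self.surface == UNINTELLIGIBLE

    def n_morphemes(self, codebooks: dict[str, Codebook]) -> int:
        """Free morpheme (the word) plus attached bound-morphology units."""
        if self.is_unintelligible:
            return 0
        bound = sum(codebooks["noun"].is_morphology(u) for u in self.noun_units)
        bound += sum(codebooks["verb"].is_morphology(u) for u in self.verb_units)
        return 1 + bound


@dataclass(frozen=True)
class Utterance:
    index: int
    tokens: tuple[Token, ...]

    def __post_init__(self) -> None:
        if not self.tokens:
            raise TranscriptError(f"utterance {self.index} is empty")

    def n_morphemes(self, codebooks: dict[str, Codebook]) -> int:
        return sum(t.n_morphemes(codebooks) for t in self.tokens)


@dataclass
class Transcript:
    child_id: str
    utterances: tuple[Utterance, ...]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.child_id:
            raise TranscriptError("child_id must be nonempty")
        for i, u in enumerate(self.utterances):
            if u.index != i:
                raise TranscriptError(
                    f"{self.child_id}: utterance indices must be contiguous "
                    f"from 0 (got {u.index} at position {i})")

    @property
    def n_utterances(self) -> int:
        return len(self.utterances)

    @property
    def tokens(self) -> list[Token]:
        return [t for u in self.utterances for t in u.tokens]

    def __eq__(self, other) -> bool:
        if not isinstance(other, Transcript):
            return NotImplemented
        return (self.child_id == other.child_id
                and self.utterances == other.utterances)


@dataclass(frozen=True)
class SpeechDescriptives:
    """Traditional language-sample measures for one transcript."""

    child_id: str
    total_utterances: int
    mlu: float  # morphemes per utterance
    ttr: float  # type-token ratio over normalized surfaces
    noun_tokens: int
    noun_types: int
    verb_tokens: int
    verb_types: int


# ---------------------------------------------------------------------------
# construction and IO

def build_transcript(child_id: str,
                     utterance_tokens: list[list[tuple]],
                     codebooks: dict[str, Codebook] | None = None,
                     metadata: dict | None = None) -> Transcript:
    """Build a validated Transcript from per-utterance token specs.

    Each token spec is ``(surface, noun_units, verb_units)`` with unit lists
    given as iterables of labels.
    """
    codebooks = codebooks or default_codebooks()
    utts = []
    pos = 0
    for ui, toks in enumerate(utterance_tokens):
        tokens = []
        for surface, nu, vu in toks:
            tokens.append(_make_token(surface, nu, vu, ui, pos, codebooks,
                                      where=f"{child_id} utt {ui}"))
            pos += 1
        utts.append(Utterance(index=ui, tokens=tuple(tokens)))
    return Transcript(child_id=child_id, utterances=tuple(utts),
                      metadata=dict(metadata or {}))


def _make_token(surface, noun_units, verb_units, ui, pos, codebooks, where):
    surface = normalize_surface(surface)
    if not surface:
        raise TranscriptError(f"{where}: empty surface form")
    nu, vu = tuple(noun_units), tuple(verb_units)
    for u in nu:
        if u not in codebooks["noun"]:
            raise TranscriptError(
                f"{where}: unknown noun-related unit {u!r} on token {surface!r}")
    for u in vu:
        if u not in codebooks["verb"]:
            raise TranscriptError(
                f"{where}: unknown verb-related unit {u!r} on token {surface!r}")
    return Token(surface=surface, noun_units=nu, verb_units=vu,
                 utterance_index=ui, position=pos)


def _parse_units(cell) -> tuple[str, ...]:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)):
        return ()
    cell = str(cell).strip()
    if not cell:
        return ()
    return tuple(part.strip() for part in cell.split("+") if part.strip())


def _frame_to_transcripts(df: pd.DataFrame, codebooks, source) -> list[Transcript]:
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise TranscriptError(f"{source}: missing columns {missing}")
    transcripts = []
    for child_id, g in df.groupby("child_id", sort=False):
        try:
            g = g.copy()
            g["utterance_index"] = g["utterance_index"].astype(int)
            g["token_index"] = g["token_index"].astype(int)
        except (TypeError, ValueError) as exc:
            raise TranscriptError(f"{source}: non-integer index ({exc})") from exc
        g = g.sort_values(["utterance_index", "token_index"])
        utt_specs = []
        for ui, ug in g.groupby("utterance_index", sort=True):
            if ui != len(utt_specs):
                raise TranscriptError(
                    f"{source}: child {child_id}: utterance indices not "
                    f"contiguous from 0 (got {ui})")
            utt_specs.append([
                (row.surface, _parse_units(row.noun_units),
                 _parse_units(row.verb_units))
                for row in ug.itertuples()
            ])
        transcripts.append(
            build_transcript(str(child_id), utt_specs, codebooks))
    return transcripts


def _read_frame(path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    try:
        return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    except Exception as exc:  # pandas raises a zoo of parse errors
        raise TranscriptError(f"{path}: cannot parse ({exc})") from exc


def read_transcript(path, codebooks: dict[str, Codebook] | None = None
                    ) -> Transcript:
    """Read a single-child transcript file in the tidy token dialect."""
    codebooks = codebooks or default_codebooks()
    ts = _frame_to_transcripts(_read_frame(path), codebooks, str(path))
    if len(ts) != 1:
        raise TranscriptError(
            f"{path}: expected exactly one child, found {len(ts)}")
    return ts[0]


def read_cohort(path, codebooks: dict[str, Codebook] | None = None
                ) -> list[Transcript]:
    """Read a pooled file, or a directory of per-child files."""
    codebooks = codebooks or default_codebooks()
    path = Path(path)
    if path.is_dir():
        out: list[Transcript] = []
        for f in sorted(path.glob("*.csv")) + sorted(path.glob("*.tsv")):
            out.extend(_frame_to_transcripts(_read_frame(f), codebooks, str(f)))
        return out
    return _frame_to_transcripts(_read_frame(path), codebooks, str(path))


def transcript_frame(t: Transcript) -> pd.DataFrame:
    rows = []
    for u in t.utterances:
        for ti, tok in enumerate(u.tokens):
            rows.append({
                "child_id": t.child_id,
                "utterance_index": u.index,
                "token_index": ti,
                "surface": tok.surface,
                "noun_units": "+".join(tok.noun_units),
                "verb_units": "+".join(tok.verb_units),
            })
    return pd.DataFrame(rows, columns=COLUMNS)


def write_transcript(t: Transcript, path) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    # newline-stable output so identical transcripts are byte-identical
    buf = io.StringIO()
    transcript_frame(t).to_csv(buf, sep=sep, index=False, lineterminator="\n")
    path.write_text(buf.getvalue(), encoding="utf-8")


def write_cohort(transcripts: list[Transcript], outdir) -> list[Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for t in transcripts:
        p = outdir / f"{t.child_id}.csv"
        write_transcript(t, p)
        paths.append(p)
    return paths


# ---------------------------------------------------------------------------
# descriptives and cohort filtering

def speech_descriptives(t: Transcript,
                        codebooks: dict[str, Codebook] | None = None
                        ) -> SpeechDescriptives:
    """MLU (in morphemes), TTR, and noun/verb token and type counts.

    Unintelligible tokens (``xxx``) contribute neither morphemes nor
    word tokens/types.
    """
    codebooks = codebooks or default_codebooks()
    if t.n_utterances == 0:
        raise TranscriptError(f"{t.child_id}: no utterances; MLU undefined")
    morphemes = sum(u.n_morphemes(codebooks) for u in t.utterances)
    words = [tok for tok in t.tokens if not tok.is_unintelligible]
    n_tokens = len(words)
    n_types = len({tok.surface for tok in words})
    noun = [tok for tok in words if tok.noun_units]
    verb = [tok for tok in words if tok.verb_units]
    return SpeechDescriptives(
        child_id=t.child_id,
        total_utterances=t.n_utterances,
        mlu=morphemes / t.n_utterances,
        ttr=(n_types / n_tokens) if n_tokens else 0.0,
        noun_tokens=len(noun),
        noun_types=len({tok.surface for tok in noun}),
        verb_tokens=len(verb),
        verb_types=len({tok.surface for tok in verb}),
    )


def filter_cohort(transcripts: list[Transcript], min_utterances: int = 20
                  ) -> tuple[list[Transcript], list[Transcript]]:
    """Partition a cohort by the minimum-utterance inclusion threshold."""
    if min_utterances < 1:
        raise ValueError("min_utterances must be >= 1")
    kept = [t for t in transcripts if t.n_utterances >= min_utterances]
    excluded = [t for t in transcripts if t.n_utterances < min_utterances]
    return kept, excluded
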